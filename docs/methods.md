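# Methods

This note documents the models, parameter choices and numerical conventions
behind `coexnet`, and what the synthetic study conditions do and do not
establish about real data.

## Generative model behind the simulator

All synthetic cohorts follow a linear single-factor model per module. Module
*m* has a latent per-sample factor f<sub>m</sub> ~ N(0, 1) — by construction
its true eigengene — and member gene *g* has expression

    x_g = l_g · f_m + ε,   ε ~ N(0, σ²),

on a log-like continuous scale. Background genes are pure noise. The defaults
(5 modules × 60 genes, 1,000 background genes, 200 samples, σ = 1) define the
standard study conditions used by the test suite and the acceptance script;
the external cohort re-draws factors for preserved modules (160 samples) and
dissolves non-preserved ones into noise.

Loadings are strictly decreasing within a module with a distinct hub tier:
the first five genes load 1.0 → 0.9, the remainder 0.7 → 0.4. A single
linear ramp (1.0 → 0.4 over 60 genes) was rejected because the kME
difference between adjacent ranks (~0.01 near the top) is an order of
magnitude below kME sampling noise at n = 200 (~0.04), making "the most
connected genes" unrecoverable in principle; hub identity must be encoded
with a gap larger than the estimator's noise to be meaningful ground truth.
Closed-form pairwise correlations, cor(x_i, x_j) =
l_i l_j / √((l_i²+σ²)(l_j²+σ²)), give the oracle values used in tests.

Drug signatures are gene-level signed effect scores (the granularity the
susceptibility and interaction stages consume), not expression matrices: a
`frac_affected` subset of the target module scores
N(direction · effect_size, background_sd = 0.5), all other genes
N(0, background_sd). Default planted panels use effect_size 2 and
frac_affected 0.8 (0.3 for the near-disjoint neutral drug). Cell-type
mixtures are S·p + noise with p ~ Dirichlet(α); the phenotype is
Σ β·f<sub>m</sub> + noise over driver modules (β = 1, noise 0.5), min–max
rescaled to [0, 1] — an affine monotone map onto the unit interval, chosen
over a fixed affine-plus-clip so that rank-based statistics are exactly
preserved and no mass piles up at the boundaries.

What the simulator does **not** emulate: count noise (negative binomial
sampling), mean–variance trends, batch effects, correlated background genes,
overlapping module membership, or single-cell sparsity. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the stated linear-factor conditions, not performance on raw
RNA-seq counts; on real data the usual normalization and log transformation
are assumed upstream.

## Network construction choices

* **Correlation:** Pearson on the (log-scale) matrix; Spearman available by
  flag. **Adjacency:** unsigned |r|^β by default, signed variant by flag.
* **Soft threshold:** grid 1..20, chosen as the smallest power with
  scale-free fit R² ≥ 0.8, else argmax. The fit bins connectivities into 10
  equal-count bins and regresses log10 density on log10 mean connectivity;
  the density estimate is (count/n)/bin-width, since equal-count bins make a
  raw frequency constant by construction. Fewer than three usable bins is a
  degenerate degree distribution and raises.
* **Tree cut:** static cut at a quantile of the average-linkage merge
  heights, default 0.5, with min module size 30 — a deliberate
  simplification of dynamic tree cutting. The default matters: on the
  standard conditions the within-module merges occupy the low-height tail
  and background merges form a narrow plateau near height 1, so a cut at the
  median height separates the two regimes (planted-label agreement
  ARI ≈ 0.93, pure-noise cohorts come out all grey), whereas a cut near the
  0.99 quantile lands above the background plateau and fuses everything.
  The quantile is exposed for data with different height profiles.
* **Eigengenes:** first right singular vector of the gene-standardized
  module submatrix, rescaled to unit variance (ddof = 1), oriented so the
  mean correlation with member genes is ≥ 0; variance explained is the
  leading singular value's share. **Hubs:** ranked by kME; intramodular
  connectivity and kME are monotonically related under the factor model and
  kME is cheaper. Ties break lexicographically by gene ID everywhere a
  ranking is cut, so outputs are reproducible.
* **Module merging:** eigengene correlation graph, single-linkage
  components above the threshold (default 0.75), iterated to a fixed point
  so the operation is idempotent.

## Preservation

Density (mean off-diagonal |cor| of the module in the test cohort) and
connectivity (Pearson correlation of intramodular connectivity vectors
between cohorts) are each standardized against n_perm = 200 random gene
sets of equal size drawn from the shared gene universe excluding the module
under test; Z_summary is their mean and the replicability threshold is 2.
This is a deliberately reduced two-component version of the published
multi-statistic preservation composites.

Two properties of this null are worth knowing. First, when the test cohort
retains other structured modules, random draws include correlated genes and
the null density is slightly inflated; a fully dissolved module therefore
scores mildly negative (typically −2 < Z < 0) rather than exactly zero.
Second, if the two cohorts are numerically identical, every permutation
yields a connectivity correlation of exactly 1 and the null has zero spread;
this is reported as a degenerate-input error (sd below 1e-12) rather than an
infinite Z.

## Enrichment and localization

The overlap p-value is the exact hypergeometric upper tail P(X ≥ a)
(scipy), one-sided in the enrichment direction since every use here is an
over-representation claim; the odds ratio is the raw cross-product ratio
with +∞ on zero denominators (a Haldane–Anscombe +0.5 variant exists but is
never substituted silently). BH correction is applied per result table —
one family per call — with two documented flag rules: raw p < 0.05 and
OR > 1 for overlap calls, BH q < 0.1 for eigengene–covariate associations.
The default universe is the expression matrix's gene set; callers may pass
a narrower measured universe (e.g. genes assayed in a drug signature
platform).

Deconvolution is nonnegative least squares per sample against the signature
matrix, renormalized to the simplex — a deterministic constrained
least-squares deconvolver with the same input/output contract as
reference-profile tools built on ν-SVR, preferred here for having no tuning
parameters. An all-zero fit falls back to uniform proportions with a
warning. Associations use Spearman rank correlation throughout (robust to
the monotone rescaling in the phenotype model).

## Drug susceptibility metric

Per drug, the response gene set is the ⌈0.05·n⌉ genes with largest
|effect|; per (module, drug), z = Φ⁻¹(1 − p) of the overlap test, computed
as `norm.isf(p)` for tail accuracy, with p clipped to [1e-15, 1 − 1e-15].
Raw susceptibility is the Stouffer combination Σz/√(n_drugs) (mean and max
variants behind a flag), and the scaled metric standardizes raw values
across modules (ddof = 1). The combination rule is this package's concrete
realization of a verbally specified "common downstream effect" composite,
and is documented as a design choice, not a canonical formula. Consequences
of the clipping: once a drug saturates the enrichment ceiling the metric
plateaus, so the scaled score is monotone in planted signal only up to the
ceiling. Thresholding is direction-agnostic (|score|) by design —
directionality is the interaction stage's question. Column order is
canonicalized before the float reduction so results are drug-order
invariant to the last bit.

## Directional interaction

Signature membership for the overlap test is every gene present in the
signature; callers apply their own differential-expression pre-filter
(`DrugSignature.filter_abs`; the examples use |score| ≥ 3 background SD).
Discordance classifies shared genes by sign pairs; zero scores form their
own category, excluded from fractions and reported as a count. The KS
comparison treats the two effect-score vectors over the shared genes as two
independent samples of equal size (unpaired); D is computed exactly over
the pooled points and the p-value from the asymptotic Kolmogorov series
truncated below 1e-18, with no small-sample exact computation or continuity
correction. A paired alternative (sign tests on per-gene differences) can
be assembled from the discordance output but is not the default. Overlaps
smaller than `min_overlap` (default 2) skip the KS fields and still report
per-gene sign agreement.

## Reproducibility

A single integer seed feeds named substreams (`coexnet.substream(seed,
stage)`) via CRC32 spawn keys, so each stage's randomness is independent and
stable when stages are re-run in isolation. All writers use a fixed float
format (`%.17g`, round-trips doubles exactly) and deterministic sort orders;
pipeline outputs are byte-identical across reruns with the same inputs,
config and seed. Problem sizes in the test suite and acceptance script
follow the default study conditions above (20-seed replications for
recovery and calibration checks, 40 for the susceptibility ranking, 200
permutations for preservation).

## Known limitations

* Static quantile tree cut, not dynamic hybrid cutting; very unbalanced
  height profiles may need a different `cut_quantile`.
* Preservation uses two sub-statistics, not the full published composite;
  its null is mildly conservative when the test cohort is partly structured
  (see above).
* Single-membership modules; no block-wise construction for very large
  (>30k gene) matrices; no consensus networks across cohorts.
* The susceptibility aggregation and the drug-set threshold (top 5%) are
  package conventions; rankings, not absolute values, are the intended
  read-out.
* Deconvolution assumes the signature matrix spans the mixture and is
  identifiable (full column rank on the shared genes); it estimates relative,
  not absolute, proportions.
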