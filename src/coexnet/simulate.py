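"""Synthetic data with planted structure for every pipeline stage.

The generative model is a linear single-factor model per module: module m has
a latent per-sample factor f_m ~ N(0, 1) (its true eigengene), and each member
gene g has expression

    x_g = l_g * f_m + eps,   eps ~ N(0, noise_sd^2),

with loadings l_g strictly decreasing within the module: a hub tier (the
first five genes, loadings 1.0 down to 0.9) followed by the bulk (0.7 down
to 0.4), so "most connected gene" is well-defined and statistically
identifiable ground truth. Background
genes are pure noise. Companion generators produce an external cohort with a
chosen subset of modules preserved, a multi-drug perturbation panel with
planted module targets, cell-type mixtures from a known signature matrix, and
a continuous phenotype (an sTIL-like fraction in [0, 1]) driven by selected
module factors. All draws go through named substreams of one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .types import DrugSignature, DrugSignatureSet

__all__ = [
    "GroundTruth",
    "DrugSpec",
    "simulate_cohort",
    "simulate_external_cohort",
    "simulate_drug_panel",
    "simulate_mixtures",
    "simulate_phenotype",
    "signature_matrix_from_truth",
    "markers_from_signature_matrix",
]

HUB_LOADING = 1.0
MIN_LOADING = 0.4
N_HUBS = 5  # leading genes per module forming the high-loading hub tier


def _module_loadings(size: int) -> np.ndarray:
    """Strictly decreasing loadings with a distinct hub tier.

    The first ``N_HUBS`` genes load from 1.0 down to 0.9 (the hubs); the
    remainder from 0.7 down to ``MIN_LOADING``. The gap between the tiers
    keeps "most connected gene" statistically identifiable at realistic
    noise, which a single linear ramp does not.
    """
    n_hub = min(N_HUBS, size)
    hub = np.linspace(HUB_LOADING, 0.9, n_hub)
    if size <= n_hub:
        return hub
    bulk = np.linspace(0.7, MIN_LOADING, size - n_hub)
    return np.concatenate([hub, bulk])


@dataclass
class DrugSpec:
    """One planted perturbation: which module it hits, how, and how hard."""

    name: str
    target_module: int
    direction: int  # +1 up-regulates the module's genes, -1 down-regulates
    effect_size: float
    frac_affected: float


@dataclass
class GroundTruth:
    """Recorded generative state, the reference for every recovery test."""

    module_labels: pd.Series  # gene -> int module id, 0 = background
    loadings: pd.Series  # gene -> loading in [0, 1]; background genes 0
    factors: pd.DataFrame  # module id (str index) x sample latent factors
    noise_sd: float
    preserved_modules: set[int] = field(default_factory=set)
    drug_map: dict[str, DrugSpec] = field(default_factory=dict)
    drug_affected: dict[str, list[str]] = field(default_factory=dict)
    phenotype_drivers: set[int] = field(default_factory=set)

    @property
    def planted_modules(self) -> list[int]:
        return sorted({int(m) for m in self.module_labels.unique() if m != 0})

    def module_genes(self, module: int) -> list[str]:
        return list(self.module_labels.index[self.module_labels == module])


def simulate_cohort(
    n_genes: int = 1300,
    n_samples: int = 200,
    n_modules: int = 5,
    module_size: int = 60,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Primary cohort: planted coexpression modules plus background genes.

    Genes are named ``G0001``... with the first ``n_modules * module_size``
    genes carrying the planted modules (module 1 first, hubs first within
    each module) and the remainder pure-noise background.
    """
    if n_modules * module_size > n_genes:
        raise ValueError(
            f"{n_modules} modules x {module_size} genes exceed n_genes={n_genes}"
        )
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be > 0, got {noise_sd}")
    rng = substream(seed, "cohort")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"S{j + 1:04d}" for j in range(n_samples)]
    labels = np.zeros(n_genes, dtype=int)
    loadings = np.zeros(n_genes)
    factors = rng.standard_normal((n_modules, n_samples))
    expr = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for m in range(n_modules):
        lo, hi = m * module_size, (m + 1) * module_size
        labels[lo:hi] = m + 1
        l = _module_loadings(module_size)
        loadings[lo:hi] = l
        expr[lo:hi, :] += l[:, None] * factors[m][None, :]
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=genes, name="module"),
        loadings=pd.Series(loadings, index=genes, name="loading"),
        factors=pd.DataFrame(
            factors, index=[str(m + 1) for m in range(n_modules)], columns=samples
        ),
        noise_sd=float(noise_sd),
    )
    return pd.DataFrame(expr, index=genes, columns=samples), truth


def simulate_external_cohort(
    truth: GroundTruth,
    preserved_labels,
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Validation cohort: preserved modules keep their loadings, others dissolve.

    Preserved modules reuse the reference loadings with freshly drawn factors;
    non-preserved modules lose their structure entirely — their genes become
    background noise in the new cohort.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    preserved = {int(m) for m in preserved_labels}
    unknown = preserved - set(truth.planted_modules)
    if unknown:
        raise ValueError(f"unknown module label(s): {sorted(unknown)}")
    rng = substream(seed, "external_cohort")
    genes = list(truth.module_labels.index)
    samples = [f"T{j + 1:04d}" for j in range(n_samples)]
    expr = rng.normal(0.0, truth.noise_sd, size=(len(genes), n_samples))
    for m in truth.planted_modules:
        if m not in preserved:
            continue
        idx = np.flatnonzero(truth.module_labels.values == m)
        factor = rng.standard_normal(n_samples)
        expr[idx, :] += truth.loadings.values[idx][:, None] * factor[None, :]
    truth.preserved_modules = preserved
    return pd.DataFrame(expr, index=genes, columns=samples)


def simulate_drug_panel(
    truth: GroundTruth,
    drugs: list[DrugSpec],
    background_sd: float = 0.5,
    seed: int = 0,
) -> DrugSignatureSet:
    """Per-drug signed effect scores over the whole gene universe.

    For each drug, a ``frac_affected`` subset of its target module's genes
    scores Normal(direction * effect_size, background_sd); every other gene
    scores Normal(0, background_sd). An opposing pair is two drugs with the
    same target module and directions +1/-1; a neutral drug targets a
    disjoint module.
    """
    panel = DrugSignatureSet()
    planted = set(truth.planted_modules)
    genes = list(truth.module_labels.index)
    for spec in drugs:
        if spec.target_module not in planted:
            raise ValueError(f"unknown target module {spec.target_module}")
        if spec.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < spec.frac_affected <= 1:
            raise ValueError("frac_affected must be in (0, 1]")
        if spec.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        rng = substream(seed, f"drug:{spec.name}")
        target_genes = truth.module_genes(spec.target_module)
        n_aff = max(1, int(round(spec.frac_affected * len(target_genes))))
        affected = sorted(rng.choice(target_genes, size=n_aff, replace=False))
        scores = pd.Series(
            rng.normal(0.0, background_sd, size=len(genes)), index=genes, name=spec.name
        )
        scores.loc[affected] += spec.direction * spec.effect_size
        panel.add(DrugSignature(name=spec.name, scores=scores))
        truth.drug_map[spec.name] = spec
        truth.drug_affected[spec.name] = affected
    return panel


def simulate_mixtures(
    signature_matrix: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha=1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk mixtures from a genes x cell-types signature matrix.

    Each sample's bulk profile is S @ p + Normal(0, noise_sd) with cell-type
    proportions p ~ Dirichlet(alpha); the true proportion matrix
    (samples x cell types, rows on the simplex) is returned alongside.
    """
    s = signature_matrix.values.astype(float)
    k = s.shape[1]
    if np.linalg.matrix_rank(s) < k:
        raise ValueError("signature matrix is rank-deficient")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,))
    rng = substream(seed, "mixtures")
    p = rng.dirichlet(alpha, size=n_samples)  # samples x celltypes
    bulk = s @ p.T + rng.normal(0.0, noise_sd, size=(s.shape[0], n_samples))
    samples = [f"M{j + 1:04d}" for j in range(n_samples)]
    expr = pd.DataFrame(bulk, index=signature_matrix.index, columns=samples)
    props = pd.DataFrame(p, index=samples, columns=signature_matrix.columns)
    return expr, props


def simulate_phenotype(
    truth: GroundTruth,
    driver_modules,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Continuous per-sample phenotype driven by selected module factors.

    phenotype_raw = sum_m beta * f_m + Normal(0, noise_sd), affinely rescaled
    (min-max over the cohort) into [0, 1] — a fraction-valued phenotype like
    a stromal TIL burden estimate.
    """
    drivers = {int(m) for m in driver_modules}
    unknown = drivers - set(truth.planted_modules)
    if unknown:
        raise ValueError(f"unknown driver module(s): {sorted(unknown)}")
    rng = substream(seed, "phenotype")
    samples = truth.factors.columns
    raw = rng.normal(0.0, noise_sd, size=len(samples))
    for m in sorted(drivers):
        raw = raw + beta * truth.factors.loc[str(m)].values
    span = raw.max() - raw.min()
    scaled = (raw - raw.min()) / span if span > 0 else np.full_like(raw, 0.5)
    truth.phenotype_drivers = drivers
    return pd.Series(scaled, index=samples, name="phenotype")


def signature_matrix_from_truth(
    truth: GroundTruth,
    marker_strength: float = 2.0,
    baseline: float = 0.1,
    include_background_type: bool = True,
) -> pd.DataFrame:
    """Cell-type signature matrix with one cell type per planted module.

    Module m's genes mark cell type ``CT{m}`` with expression proportional to
    their planted loadings; an optional extra column models a cell type with
    flat expression over background genes. Values are non-negative, as a
    deconvolution basis requires.
    """
    genes = list(truth.module_labels.index)
    cols = {}
    for m in truth.planted_modules:
        col = np.full(len(genes), baseline)
        idx = np.flatnonzero(truth.module_labels.values == m)
        col[idx] = baseline + marker_strength * truth.loadings.values[idx]
        cols[f"CT{m}"] = col
    if include_background_type:
        col = np.full(len(genes), baseline)
        bg = np.flatnonzero(truth.module_labels.values == 0)
        col[bg] = baseline + marker_strength * 0.5
        cols["CT_other"] = col
    return pd.DataFrame(cols, index=genes)


def markers_from_signature_matrix(
    signature_matrix: pd.DataFrame, top_n: int = 50
) -> "dict[str, list[str]]":
    """Top marker genes per cell type: the ``top_n`` most specific rows.

    Specificity of gene g for type k is S_gk minus the best alternative
    column, so shared-baseline genes never become markers.
    """
    markers = {}
    s = signature_matrix.values.astype(float)
    for j, ct in enumerate(signature_matrix.columns):
        others = np.delete(s, j, axis=1)
        spec = s[:, j] - others.max(axis=1)
        order = np.argsort(-spec, kind="stable")[:top_n]
        markers[ct] = [signature_matrix.index[i] for i in sorted(order)]
    return markers
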