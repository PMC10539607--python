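"""Directional intersection of two drug-response signatures.

Given two signatures of signed per-gene effects (say an opioid-induced and
an immune-checkpoint-inhibition-induced signature), three questions are
asked on their shared gene set: do they overlap more than chance (Fisher
one-sided), do they push shared genes in the same or opposite directions
(sign-quadrant discordance fractions), and do they induce the same
distribution of effect sizes (two-sample Kolmogorov-Smirnov on the two
score vectors over the overlap)? The composed report captures a
concordant-vs-opposing verdict for any pair — e.g. an opposing
opioid-vs-ICI pair versus a near-disjoint, concordant ketamine-vs-ICI pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import fisher_overlap
from .types import DrugSignature, EnrichmentResult

__all__ = [
    "signature_overlap",
    "directional_discordance",
    "ks_two_sample",
    "ks_asymptotic_pvalue",
    "build_interaction_report",
    "InteractionReport",
]


def signature_overlap(
    sig_a: DrugSignature,
    sig_b: DrugSignature,
    universe,
    alpha: float = 0.05,
    or_threshold: float = 1.0,
) -> tuple[list[str], EnrichmentResult]:
    """Gene-ID intersection of two signatures plus its Fisher overlap test.

    Signature membership is every gene present in the signature (callers
    apply their own differential-expression pre-filter). The significance
    flag uses the overlap rule p < alpha and odds ratio > or_threshold.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    genes_a = sig_a.genes & universe
    genes_b = sig_b.genes & universe
    overlap = sorted(genes_a & genes_b)
    res = fisher_overlap(genes_a, genes_b, universe)
    res.significant = res.flag(alpha=alpha, or_threshold=or_threshold)
    return overlap, res


def directional_discordance(
    sig_a: DrugSignature, sig_b: DrugSignature, overlap_genes
) -> dict:
    """Sign-quadrant classification of the shared genes.

    Reports, among genes up-regulated by B, the fraction down- and
    up-regulated by A (and likewise for B-down genes), plus the overall
    discordance — the fraction of shared genes whose two effect signs
    disagree. Zero scores form their own category: they are excluded from
    the fractions and reported as a count.
    """
    overlap_genes = list(overlap_genes)
    for g in overlap_genes:
        if g not in sig_a.scores.index:
            raise ValueError(f"gene {g!r} missing a score in signature {sig_a.name!r}")
        if g not in sig_b.scores.index:
            raise ValueError(f"gene {g!r} missing a score in signature {sig_b.name!r}")
    sa = np.sign(sig_a.scores.loc[overlap_genes].values)
    sb = np.sign(sig_b.scores.loc[overlap_genes].values)
    nonzero = (sa != 0) & (sb != 0)
    n_zero = int((~nonzero).sum())
    sa_nz, sb_nz = sa[nonzero], sb[nonzero]

    def _frac(mask_b, sign_a):
        n = int(mask_b.sum())
        if n == 0:
            return float("nan"), 0
        return float((sa_nz[mask_b] == sign_a).sum() / n), n

    b_up = sb_nz > 0
    b_down = sb_nz < 0
    frac_bup_adown, n_bup = _frac(b_up, -1)
    frac_bup_aup, _ = _frac(b_up, +1)
    frac_bdown_aup, n_bdown = _frac(b_down, +1)
    frac_bdown_adown, _ = _frac(b_down, -1)
    n_nz = int(nonzero.sum())
    overall = float((sa_nz * sb_nz < 0).sum() / n_nz) if n_nz else float("nan")
    return {
        "n_overlap": len(overlap_genes),
        "n_zero_score": n_zero,
        "n_b_up": n_bup,
        "n_b_down": n_bdown,
        "frac_b_up_a_down": frac_bup_adown,
        "frac_b_up_a_up": frac_bup_aup,
        "frac_b_down_a_up": frac_bdown_aup,
        "frac_b_down_a_down": frac_bdown_adown,
        "overall_discordance": overall,
    }


def ks_two_sample(x, y) -> tuple[float, float]:
    """Exact two-sample KS statistic and its asymptotic two-sided p-value.

    D = sup_t |F_x(t) - F_y(t)| evaluated exactly over the pooled sample
    points; the p-value comes from the asymptotic Kolmogorov distribution
    (:func:`ks_asymptotic_pvalue`).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"need >= 2 observations per sample, got {x.size} and {y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / xs.size
    cdf_y = np.searchsorted(ys, pooled, side="right") / ys.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    return d, ks_asymptotic_pvalue(d, xs.size, ys.size)


def ks_asymptotic_pvalue(d: float, n: int, m: int) -> float:
    """Two-sided asymptotic KS p-value from the Kolmogorov series.

    With lambda = sqrt(n m / (n + m)) * D,
    p = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2), truncated once terms
    drop below 1e-18 and clamped to [0, 1]. No small-sample exact
    computation and no continuity correction.
    """
    if not (math.isfinite(d) and 0.0 <= d <= 1.0):
        raise ValueError(f"D must be in [0, 1], got {d!r}")
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    lam = math.sqrt(n * m / (n + m)) * d
    if lam == 0.0:
        return 1.0
    total = 0.0
    for k in range(1, 100_001):
        term = math.exp(-2.0 * k * k * lam * lam)
        if term < 1e-18:
            break
        total += term if k % 2 == 1 else -term
    return min(1.0, max(0.0, 2.0 * total))


@dataclass
class InteractionReport:
    """Composed overlap + directionality + distribution comparison."""

    sig_a: str
    sig_b: str
    overlap_genes: list[str]
    overlap: EnrichmentResult
    discordance: dict
    ks_d: float | None
    ks_p: float | None
    pair_table: pd.DataFrame = field(repr=False, default=None)  # gene, score_a, score_b

    def to_dict(self) -> dict:
        return {
            "sig_a": self.sig_a,
            "sig_b": self.sig_b,
            "overlap_genes": list(self.overlap_genes),
            "overlap": self.overlap.to_dict(),
            "discordance": self.discordance,
            "ks_d": self.ks_d,
            "ks_p": self.ks_p,
            "pairs": [
                {"gene": g, "score_a": float(a), "score_b": float(b)}
                for g, a, b in self.pair_table.itertuples(index=False)
            ]
            if self.pair_table is not None
            else [],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "InteractionReport":
        d = json.loads(text)
        ov = d["overlap"]
        overlap = EnrichmentResult(
            a=ov["a"], b=ov["b"], c=ov["c"], d=ov["d"],
            odds_ratio=ov["odds_ratio"], p_value=ov["p_value"],
            q_value=ov["q_value"], significant=ov["significant"],
        )
        pairs = pd.DataFrame(d["pairs"], columns=["gene", "score_a", "score_b"])
        return cls(
            sig_a=d["sig_a"], sig_b=d["sig_b"], overlap_genes=d["overlap_genes"],
            overlap=overlap, discordance=d["discordance"],
            ks_d=d["ks_d"], ks_p=d["ks_p"], pair_table=pairs,
        )


def build_interaction_report(
    sig_a: DrugSignature,
    sig_b: DrugSignature,
    universe,
    alpha: float = 0.05,
    or_threshold: float = 1.0,
    min_overlap: int = 2,
) -> InteractionReport:
    """Run overlap, discordance and KS on a signature pair.

    The KS comparison treats the two effect-score vectors over the shared
    genes as two unpaired samples of equal size. Below ``min_overlap``
    shared genes the KS fields are left null and only the overlap statistics
    are reported (small overlaps — e.g. a three-gene intersection — still
    get their per-gene sign agreements in the pair table).
    """
    overlap, res = signature_overlap(
        sig_a, sig_b, universe, alpha=alpha, or_threshold=or_threshold
    )
    pair_table = pd.DataFrame(
        {
            "gene": overlap,
            "score_a": sig_a.scores.loc[overlap].values if overlap else [],
            "score_b": sig_b.scores.loc[overlap].values if overlap else [],
        }
    )
    discordance = (
        directional_discordance(sig_a, sig_b, overlap)
        if overlap
        else {"n_overlap": 0}
    )
    if len(overlap) >= max(min_overlap, 2):
        ks_d, ks_p = ks_two_sample(
            pair_table["score_a"].values, pair_table["score_b"].values
        )
    else:
        ks_d, ks_p = None, None
    return InteractionReport(
        sig_a=sig_a.name,
        sig_b=sig_b.name,
        overlap_genes=overlap,
        overlap=res,
        discordance=discordance,
        ks_d=ks_d,
        ks_p=ks_p,
        pair_table=pair_table,
    )
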