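"""Gene-set over-representation: one-sided Fisher overlap with BH correction.

This is the workhorse behind functional annotation of modules, cell-type
specificity calls, TF-target/kinase-substrate library tests, and
drug-signature overlap. The p-value is the hypergeometric upper tail
P(X >= a) for the observed 2x2 overlap table; the odds ratio is the raw
cross-product ratio, matching how over-representation results are
conventionally printed. Multiple testing is corrected per calling family
with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import GREY, EnrichmentResult, GeneSetLibrary

__all__ = ["fisher_overlap", "bh_adjust", "enrich_modules"]


def fisher_overlap(set_a, set_b, universe) -> EnrichmentResult:
    """One-sided (enrichment direction) Fisher overlap of two gene sets.

    Genes outside the universe are dropped (their count is recorded on the
    result). With |universe| = N, |A| = K, |B| = n and a = |A ∩ B|, the
    p-value is the hypergeometric tail P(X >= a), X ~ Hypergeom(N, K, n).
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    a_all = {str(g) for g in set_a}
    b_all = {str(g) for g in set_b}
    a_set = a_all & universe
    b_set = b_all & universe
    n_dropped = (len(a_all) - len(a_set)) + (len(b_all) - len(b_set))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene(s) outside the universe were dropped", stacklevel=2
        )
    a = len(a_set & b_set)
    b = len(a_set) - a
    c = len(b_set) - a
    d = len(universe) - a - b - c
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = 0.0
    # upper tail P(X >= a); sf(a-1) includes a itself
    p = float(hypergeom.sf(a - 1, len(universe), len(a_set), len(b_set)))
    p = min(max(p, 0.0), 1.0) or np.nextafter(0, 1)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d, odds_ratio=float(odds), p_value=p, n_dropped=n_dropped
    )


def fisher_overlap_haldane(set_a, set_b, universe) -> EnrichmentResult:
    """Variant with the Haldane-Anscombe +0.5 cell correction on the odds ratio.

    Never substituted silently for the raw cross-product ratio; offered for
    tables with zero cells where a finite effect size is wanted.
    """
    res = fisher_overlap(set_a, set_b, universe)
    res.odds_ratio = ((res.a + 0.5) * (res.d + 0.5)) / ((res.b + 0.5) * (res.c + 0.5))
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped to 1; always >= the raw p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich_modules(
    modules: pd.Series,
    library: GeneSetLibrary,
    universe=None,
    alpha: float = 0.05,
    or_threshold: float = 1.0,
) -> pd.DataFrame:
    """Test every (non-grey module, library set) pair for over-representation.

    The universe defaults to all genes carrying a module label (i.e. the
    expression matrix's genes). BH is applied across the whole returned
    table — one multiple-testing family per call — and rows are sorted by
    q, then p, then (module, set) for determinism.
    """
    if universe is None:
        universe = set(modules.index.astype(str))
    else:
        universe = {str(g) for g in universe}
    rows = []
    module_names = sorted(m for m in modules.unique() if m != GREY)
    for m in module_names:
        genes_m = set(modules.index[modules == m].astype(str))
        for set_name in library:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fisher_overlap(genes_m, library[set_name], universe)
            rows.append(
                {
                    "module": m,
                    "set": set_name,
                    "a": res.a,
                    "b": res.b,
                    "c": res.c,
                    "d": res.d,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                }
            )
    table = pd.DataFrame(
        rows, columns=["module", "set", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].values)
        table["significant"] = (table["p"] < alpha) & (table["odds_ratio"] > or_threshold)
        table = table.sort_values(
            ["q", "p", "module", "set"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table
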