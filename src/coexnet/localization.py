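"""Cell-type localization of modules and continuous-phenotype association.

Two complementary localization routes mirror how a module is tied to a cell
type in practice: (1) deconvolve bulk profiles against a cell-type signature
matrix and correlate module eigengenes with the estimated proportions;
(2) test module genes for over-representation in curated marker sets.
Phenotype association uses Spearman rank correlation between eigengenes and
per-sample covariates, BH-corrected across the whole table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .enrichment import bh_adjust, enrich_modules
from .types import EigengeneMatrix, GeneSetLibrary

__all__ = [
    "deconvolve",
    "correlate_eigengene_covariate",
    "celltype_specificity",
]


def deconvolve(bulk: pd.DataFrame, signature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type proportions per bulk sample.

    Solves min ||S p - b||_2 subject to p >= 0 per sample on the genes shared
    by the bulk matrix and the signature matrix, then renormalizes p to the
    simplex. A deterministic constrained-least-squares deconvolver: same
    input/output contract as reference-profile tools, no tuning parameters.
    An all-zero solution falls back to the uniform composition with a
    warning. Returns samples x cell-types.
    """
    shared = signature_matrix.index.intersection(bulk.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between bulk matrix and signature matrix")
    if len(shared) < 0.5 * signature_matrix.shape[0]:
        raise ValueError(
            f"only {len(shared)}/{signature_matrix.shape[0]} signature genes found "
            "in the bulk matrix; need at least half"
        )
    s = signature_matrix.loc[shared].values.astype(float)
    k = s.shape[1]
    if np.linalg.matrix_rank(s) < k:
        raise ValueError("signature matrix is rank-deficient on the shared genes")
    b = bulk.loc[shared].values.astype(float)
    out = np.empty((bulk.shape[1], k))
    n_fallback = 0
    for j in range(bulk.shape[1]):
        p, _ = nnls(s, b[:, j])
        total = p.sum()
        if total <= 0:
            p = np.full(k, 1.0 / k)
            n_fallback += 1
        else:
            p = p / total
        out[j] = p
    if n_fallback:
        warnings.warn(
            f"{n_fallback} sample(s) had an all-zero fit; uniform proportions used",
            stacklevel=2,
        )
    return pd.DataFrame(out, index=bulk.columns, columns=signature_matrix.columns)


def correlate_eigengene_covariate(
    eigengenes: EigengeneMatrix,
    covariates: pd.DataFrame,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Spearman correlation of every module eigengene with every covariate.

    Covariates are samples x k. Only shared samples are used (at least 10
    required); constant covariates are dropped with a warning since rank
    correlation is undefined for them. BH is applied across the full
    (module x covariate) table and a pair is flagged significant when
    q < ``fdr``.
    """
    shared = eigengenes.values.columns.intersection(covariates.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared samples, got {len(shared)}")
    eig = eigengenes.values[shared]
    cov = covariates.loc[shared]
    rows = []
    for cname in cov.columns:
        y = cov[cname].values.astype(float)
        if np.all(y == y[0]):
            warnings.warn(f"constant covariate {cname!r} dropped", stacklevel=2)
            continue
        for m in eig.index:
            rho, p = spearmanr(eig.loc[m].values, y)
            rows.append({"module": m, "covariate": cname, "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows, columns=["module", "covariate", "rho", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].values)
        table["significant"] = table["q"] < fdr
        table = table.sort_values(
            ["q", "p", "module", "covariate"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table


def celltype_specificity(
    modules: pd.Series,
    marker_library: GeneSetLibrary,
    universe=None,
    alpha: float = 0.05,
    or_threshold: float = 1.0,
) -> pd.DataFrame:
    """Marker-set over-representation per module.

    Thin wrapper over :func:`coexnet.enrichment.enrich_modules` with the
    cell-type flag rule (raw p < alpha and odds ratio > threshold); a module
    is called specific to the cell types whose marker sets it is enriched
    for.
    """
    return enrich_modules(
        modules, marker_library, universe=universe, alpha=alpha, or_threshold=or_threshold
    )
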