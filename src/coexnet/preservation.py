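"""Module preservation: does a module replicate in an external cohort?

Two complementary statistics per module, each standardized against a
permutation null of random same-size gene sets drawn from the cohorts'
shared gene universe:

* density — mean off-diagonal |cor| among the module's genes in the test
  cohort (are the genes still mutually correlated?);
* connectivity — Pearson correlation between each gene's intramodular
  connectivity (sum of |cor| to module co-members) in the reference vs the
  test cohort (is the hub structure the same?).

Z_summary is the mean of the two Z scores; modules at or above the
threshold (default 2) are called replicable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .types import GREY

__all__ = ["module_preservation", "replicable_modules"]


def _abs_cor(x: np.ndarray) -> np.ndarray:
    return np.abs(np.clip(np.corrcoef(x), -1.0, 1.0))


def _density(acor: np.ndarray) -> float:
    n = acor.shape[0]
    off = acor[np.triu_indices(n, k=1)]
    return float(off.mean())


def _connectivity(acor: np.ndarray) -> np.ndarray:
    return acor.sum(axis=1) - np.diag(acor)


def _conn_cor(ref: np.ndarray, test: np.ndarray) -> float:
    k_ref = _connectivity(_abs_cor(ref))
    k_test = _connectivity(_abs_cor(test))
    if k_ref.std() == 0 or k_test.std() == 0:
        return 0.0
    return float(np.corrcoef(k_ref, k_test)[0, 1])


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    modules: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-standardized preservation statistics per module.

    Returns one row per non-grey module with columns ``n_genes``,
    ``density_obs``, ``z_density``, ``z_connectivity``, ``z_summary`` and
    ``evaluable``. Modules with fewer than 3 genes shared between the
    cohorts, or sharing less than half their genes, are flagged
    not-evaluable rather than raising. A permutation null with zero spread
    (e.g. literally identical cohorts) is a degenerate input and raises.
    """
    if n_perm < 10:
        raise ValueError(f"n_perm must be >= 10, got {n_perm}")
    shared = ref_expr.index.intersection(test_expr.index)
    shared_set = set(shared)
    ref = ref_expr.loc[shared]
    test = test_expr.loc[shared]
    rng = substream(seed, "preservation")
    rows = []
    module_names = sorted(m for m in modules.unique() if m != GREY)
    shared_arr = np.array(shared)
    for m in module_names:
        genes_m = [g for g in modules.index[modules == m] if g in shared_set]
        size_total = int((modules == m).sum())
        if len(genes_m) < 3 or len(genes_m) < 0.5 * size_total:
            rows.append(
                {
                    "module": m,
                    "n_genes": len(genes_m),
                    "density_obs": np.nan,
                    "z_density": np.nan,
                    "z_connectivity": np.nan,
                    "z_summary": np.nan,
                    "evaluable": False,
                }
            )
            continue
        s = len(genes_m)
        ref_m = ref.loc[genes_m].values
        test_m = test.loc[genes_m].values
        obs_density = _density(_abs_cor(test_m))
        obs_conn = _conn_cor(ref_m, test_m)
        pool = shared_arr[~np.isin(shared_arr, genes_m)]
        if len(pool) < s:
            raise ValueError(
                f"shared gene universe too small to draw null sets for module {m!r}"
            )
        perm_density = np.empty(n_perm)
        perm_conn = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(pool, size=s, replace=False)
            ref_p = ref.loc[draw].values
            test_p = test.loc[draw].values
            perm_density[i] = _density(_abs_cor(test_p))
            perm_conn[i] = _conn_cor(ref_p, test_p)
        z_density = _zscore(obs_density, perm_density, m, "density")
        z_conn = _zscore(obs_conn, perm_conn, m, "connectivity")
        z_summary = 0.5 * (z_density + z_conn)
        rows.append(
            {
                "module": m,
                "n_genes": s,
                "density_obs": obs_density,
                "z_density": z_density,
                "z_connectivity": z_conn,
                "z_summary": z_summary,
                "evaluable": True,
            }
        )
    cols = ["module", "n_genes", "density_obs", "z_density", "z_connectivity",
            "z_summary", "evaluable"]
    return pd.DataFrame(rows, columns=cols).set_index("module")


def _zscore(obs: float, perm: np.ndarray, module, what: str) -> float:
    sd = float(perm.std(ddof=1))
    if sd < 1e-12:  # exact-copy cohorts: every null draw gives the same value
        raise ValueError(
            f"degenerate permutation null (sd = 0) for module {module!r} {what} "
            "statistic; are the two cohorts identical?"
        )
    return float((obs - perm.mean()) / sd)


def replicable_modules(result: pd.DataFrame, z_threshold: float = 2.0) -> set[str]:
    """Modules whose Z_summary meets the threshold; grey is never returned."""
    if not z_threshold > 0:
        raise ValueError(f"z_threshold must be > 0, got {z_threshold}")
    ok = result[(result["evaluable"]) & (result["z_summary"] >= z_threshold)]
    return {m for m in ok.index if m != GREY}
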