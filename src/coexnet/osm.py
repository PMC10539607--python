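"""Drug susceptibility scoring of modules against a perturbation panel.

A panel of drug signatures (signed per-gene effect scores) is reduced to one
top-responder gene set per drug; each (module, drug) pair gets an enrichment
z-score from the one-sided Fisher overlap; per-module z-scores are combined
across the panel (Stouffer by default) into a raw susceptibility metric and
standardized across modules into the scaled metric. The score is
direction-agnostic by design — it asks whether a module is robustly
modulated by the panel's shared downstream effect, not in which direction;
directionality is the interaction stage's job.

The aggregation is one concrete realization of a verbally-defined composite;
``mean`` and ``max`` alternatives are available behind the ``aggregation``
flag and the choice is documented in the methods note.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import fisher_overlap
from .types import GREY, DrugSignature, DrugSignatureSet

__all__ = ["drug_response_geneset", "network_drug_zscores", "osm_scores"]

#: p-values are clipped into this open interval before the normal inversion.
P_CLIP = 1e-15


def drug_response_geneset(signature: DrugSignature, top_fraction: float = 0.05) -> list[str]:
    """The ceil(top_fraction * n) genes with largest |score|.

    Boundary ties are broken by gene ID so the set is reproducible. Returned
    as a list ordered by decreasing |score| (then ID).
    """
    if not 0.0 < top_fraction < 0.5:
        raise ValueError(f"top_fraction must be in (0, 0.5), got {top_fraction}")
    n = len(signature.scores)
    if n == 0:
        raise ValueError(f"signature {signature.name!r} is empty")
    n_top = math.ceil(top_fraction * n)
    abs_scores = signature.scores.abs()
    ranked = sorted(abs_scores.index, key=lambda g: (-abs_scores[g], g))
    return ranked[:n_top]


def network_drug_zscores(
    modules: pd.Series,
    drug_sets: dict[str, "list[str] | set[str]"],
    universe=None,
) -> pd.DataFrame:
    """Per-(module, drug) enrichment z-scores.

    z = Phi^-1(1 - p) with p the one-sided Fisher overlap p-value of the
    module's genes against the drug's top-responder set within the universe,
    clipped to [1e-15, 1 - 1e-15] before inversion. Modules with fewer than
    3 genes in the universe are omitted with a warning.
    """
    if universe is None:
        universe = set(modules.index.astype(str))
    else:
        universe = {str(g) for g in universe}
    module_names = sorted(m for m in modules.unique() if m != GREY)
    rows = {}
    for m in module_names:
        genes_m = set(modules.index[modules == m].astype(str)) & universe
        if len(genes_m) < 3:
            warnings.warn(
                f"module {m!r} has fewer than 3 genes in the universe; omitted",
                stacklevel=2,
            )
            continue
        zs = {}
        for drug, gene_set in drug_sets.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fisher_overlap(genes_m, gene_set, universe)
            p = min(max(res.p_value, P_CLIP), 1.0 - P_CLIP)
            zs[drug] = float(norm.isf(p))  # = Phi^-1(1 - p), accurate in both tails
        rows[m] = zs
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "module"
    return table


def osm_scores(z_table: pd.DataFrame, aggregation: str = "stouffer") -> pd.DataFrame:
    """Combine per-drug z-scores into raw and scaled susceptibility metrics.

    stouffer: raw_m = sum_d z_md / sqrt(n_drugs); mean: the plain average;
    max: the strongest single drug. The scaled metric is the z-score of the
    raw metric across evaluable modules (sample sd), so it is mean 0 / sd 1
    by construction and invariant to drug column order. Sorted by scaled
    metric, descending.
    """
    if z_table.shape[1] < 2:
        raise ValueError("need >= 2 drugs to combine")
    if z_table.shape[0] < 2:
        raise ValueError("need >= 2 modules to scale the metric across modules")
    # canonical column order: makes the float reduction drug-order invariant
    z_table = z_table[sorted(z_table.columns)]
    z = z_table.values.astype(float)
    n_drugs = z.shape[1]
    if aggregation == "stouffer":
        raw = z.sum(axis=1) / np.sqrt(n_drugs)
    elif aggregation == "mean":
        raw = z.mean(axis=1)
    elif aggregation == "max":
        raw = z.max(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    sd = raw.std(ddof=1)
    scaled = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
    out = z_table.copy()
    out["raw_osm"] = raw
    out["scaled_osm"] = scaled
    # tie-break by module name so the ranking is drug-order invariant
    return out.sort_index().sort_values("scaled_osm", ascending=False, kind="stable")


def panel_genesets(
    panel: DrugSignatureSet, top_fraction: float = 0.05
) -> dict[str, list[str]]:
    """Top-responder gene set for every drug in a panel."""
    return {sig.name: drug_response_geneset(sig, top_fraction) for sig in panel}
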