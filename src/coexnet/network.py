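"""Weighted coexpression network construction and module detection.

The construction follows the standard weighted-network recipe: a signed or
unsigned adjacency from pairwise Pearson correlation raised to a soft
threshold power, topological overlap to pool shared-neighbor information,
average-linkage hierarchical clustering of 1 - TOM, and a static tree cut.
Modules are summarized by eigengenes (first principal component of the
standardized module submatrix) and genes are ranked within modules by kME
(module membership, the correlation of a gene with its module eigengene),
the hub criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import GREY, EigengeneMatrix

__all__ = [
    "COLOR_PALETTE",
    "SoftThresholdReport",
    "pick_soft_threshold",
    "build_adjacency",
    "topological_overlap",
    "detect_modules",
    "compute_eigengenes",
    "module_membership",
    "hub_genes",
    "merge_close_modules",
]

#: Size-ordered module color palette; "grey" is reserved for unassigned genes.
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
)


def _check_expression(expr: pd.DataFrame) -> None:
    variances = expr.var(axis=1, ddof=1)
    zero = variances[variances == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance gene(s): {list(zero.index[:5])}")


def _correlation(expr: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    """Gene-gene correlation matrix of a genes x samples frame."""
    x = expr.values.astype(float)
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x, axis=1)
    cor = np.corrcoef(x)
    if not np.all(np.isfinite(cor)):
        raise ValueError("non-finite correlation encountered (zero-variance gene?)")
    return np.clip(cor, -1.0, 1.0)


@dataclass
class SoftThresholdReport:
    """Scale-free fit diagnostics per candidate power and the chosen power."""

    table: pd.DataFrame  # columns: power, r_squared, mean_connectivity
    chosen_power: int
    r2_target: float

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["chosen"] = out["power"] == self.chosen_power
        return out


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 density ~ log10 mean-connectivity regression.

    Connectivities are split into ``n_bins`` equal-count bins; each bin
    contributes its mean k and the density estimate (count/n)/bin_width.
    Zero-width bins (heavily tied degrees) are skipped; fewer than 3 usable
    bins is a degenerate degree distribution and raises.
    """
    order = np.argsort(connectivity, kind="stable")
    bins = np.array_split(order, n_bins)
    mean_k, dens = [], []
    n = len(connectivity)
    for b in bins:
        if len(b) < 2:
            continue
        kv = connectivity[b]
        width = float(kv.max() - kv.min())
        mk = float(kv.mean())
        if width <= 0 or mk <= 0:
            continue
        mean_k.append(mk)
        dens.append((len(b) / n) / width)
    if len(mean_k) < 3:
        raise ValueError(
            f"fewer than 3 usable connectivity bins ({len(mean_k)}); "
            "degree distribution too degenerate for a scale-free fit"
        )
    lk = np.log10(np.asarray(mean_k))
    lp = np.log10(np.asarray(dens))
    if lk.std() == 0 or lp.std() == 0:
        return 0.0
    r = np.corrcoef(lk, lp)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    mode: str = "unsigned",
    method: str = "pearson",
) -> SoftThresholdReport:
    """Scan candidate soft-threshold powers for approximate scale-free topology.

    For each power the full adjacency is built, the connectivity
    k_i = sum_{j != i} a_ij computed, degrees binned into 10 equal-count bins
    and the R^2 of the log10 frequency vs log10 mean-connectivity regression
    reported. The chosen power is the smallest with R^2 >= ``r2_target``,
    falling back to the argmax R^2 when no power reaches the target.
    """
    if expr.shape[0] < 20 or expr.shape[1] < 10:
        raise ValueError(
            f"need >= 20 genes and >= 10 samples, got {expr.shape[0]} x {expr.shape[1]}"
        )
    powers = [int(p) for p in powers]
    if any(p < 1 for p in powers):
        raise ValueError("powers must be positive integers")
    _check_expression(expr)
    cor = _correlation(expr, method)
    rows = []
    for p in powers:
        adj = _adjacency_from_cor(cor, p, mode)
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2 = _scale_free_r2(k)
        rows.append({"power": p, "r_squared": r2, "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r_squared"] >= r2_target]
    chosen = int(ok["power"].iloc[0]) if len(ok) else int(
        table.loc[table["r_squared"].idxmax(), "power"]
    )
    return SoftThresholdReport(table=table, chosen_power=chosen, r2_target=r2_target)


def _adjacency_from_cor(cor: np.ndarray, power: int, mode: str) -> np.ndarray:
    if mode == "unsigned":
        adj = np.abs(cor) ** power
    elif mode == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"mode must be 'unsigned' or 'signed', got {mode!r}")
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def build_adjacency(
    expr: pd.DataFrame,
    power: int,
    mode: str = "unsigned",
    method: str = "pearson",
) -> pd.DataFrame:
    """Soft-thresholded adjacency: |cor|^power (unsigned) or ((1+cor)/2)^power (signed)."""
    if power < 1:
        raise ValueError(f"power must be >= 1, got {power}")
    _check_expression(expr)
    cor = _correlation(expr, method)
    adj = _adjacency_from_cor(cor, power, mode)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    L_ij = sum_{u != i,j} a_iu a_uj counts shared weighted neighbors and
    k_i = sum_{u != i} a_iu; TOM_ii = 1. High overlap marks gene pairs that
    are not only connected but embedded in the same neighborhood.
    """
    a = adjacency.values.astype(float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l_mat = a0 @ a0  # zero diagonal of a0 removes the u=i and u=j terms
    k = a0.sum(axis=1)
    k_min = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l_mat + a0) / (k_min + 1.0 - a0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_quantile: float = 0.5,
) -> pd.Series:
    """Cluster genes on 1 - TOM and label modules by size-ordered colors.

    Average-linkage hierarchical clustering of the topological-overlap
    dissimilarity, cut at the ``cut_quantile`` quantile of merge heights.
    Clusters below ``min_module_size`` are relabeled "grey"; surviving
    clusters get palette colors in decreasing size order (ties broken by the
    lexicographically smallest member gene).
    """
    if min_module_size < 3:
        raise ValueError(f"min_module_size must be >= 3, got {min_module_size}")
    if not 0.0 < cut_quantile < 1.0:
        raise ValueError(f"cut_quantile must be in (0, 1), got {cut_quantile}")
    diss = 1.0 - tom.values
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    cut_height = float(np.quantile(z[:, 2], cut_quantile))
    raw = fcluster(z, t=cut_height, criterion="distance")
    return _labels_from_clusters(pd.Series(raw, index=tom.index), min_module_size)


def _labels_from_clusters(raw: pd.Series, min_module_size: int) -> pd.Series:
    """Relabel integer clusters as size-ordered palette colors, small -> grey."""
    labels = pd.Series(GREY, index=raw.index, dtype=object, name="module")
    sizes = raw.value_counts()
    keep = sizes[sizes >= min_module_size]
    # order: size descending, then smallest member gene for determinism
    order = sorted(
        keep.index,
        key=lambda c: (-int(keep[c]), min(raw.index[raw == c])),
    )
    if len(order) > len(COLOR_PALETTE):
        raise ValueError(
            f"{len(order)} modules exceed the {len(COLOR_PALETTE)}-color palette; "
            "raise min_module_size or the cut height"
        )
    for color, cluster in zip(COLOR_PALETTE, order):
        labels[raw == cluster] = color
    return labels


def compute_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> EigengeneMatrix:
    """First principal component summary of each module, per sample.

    Each module's genes are standardized across samples; the eigengene is the
    leading right singular vector scaled to unit variance and oriented so
    that its mean correlation with the module's genes is non-negative.
    Variance explained is the leading singular value's share of total
    variance.
    """
    labels = [m for m in _module_sizes(modules).index if m != GREY]
    values = {}
    var_exp = {}
    for m in labels:
        genes = modules.index[modules == m]
        if len(genes) < 2:
            raise ValueError(f"module {m!r} has fewer than 2 genes")
        sub = expr.loc[genes].values.astype(float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {m!r}")
        std = (sub - mu) / sd
        u, s, vt = np.linalg.svd(std, full_matrices=False)
        pc = vt[0]
        pc = pc - pc.mean()
        pc_sd = pc.std(ddof=1)
        if pc_sd == 0:
            raise ValueError(f"degenerate eigengene for module {m!r}")
        pc = pc / pc_sd
        # orient: mean correlation with member genes >= 0
        cors = (std @ pc) / ((std.shape[1] - 1))
        if cors.mean() < 0:
            pc = -pc
        values[m] = pc
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(values, index=expr.columns).T
    eig.index.name = "module"
    return EigengeneMatrix(
        values=eig, variance_explained=pd.Series(var_exp, name="variance_explained")
    )


def _module_sizes(modules: pd.Series) -> pd.Series:
    sizes = modules.value_counts()
    # deterministic order: size desc then name
    return sizes.sort_index().sort_values(ascending=False, kind="stable")


def module_membership(expr: pd.DataFrame, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """kME matrix: Pearson correlation of every gene with every module eigengene."""
    _check_expression(expr)
    x = expr.values.astype(float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    e = eigengenes.values.values.astype(float)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=1, keepdims=True)
    n = x.shape[1]
    kme = (xz @ ez.T) / (n - 1)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.index, columns=eigengenes.values.index)


def hub_genes(
    kme: pd.DataFrame,
    modules: pd.Series,
    top_n: int | None = None,
    kme_min: float | None = None,
) -> dict[str, list[str]]:
    """Rank each module's own genes by kME and return the hubs.

    Exactly one of ``top_n`` (the n most connected genes) or ``kme_min``
    (all genes above a kME floor) selects the hub rule. Ties are broken by
    gene ID so hub lists are reproducible.
    """
    if (top_n is None) == (kme_min is None):
        raise ValueError("specify exactly one of top_n or kme_min")
    if top_n is not None and top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if kme_min is not None and not 0.0 < kme_min < 1.0:
        raise ValueError(f"kme_min must be in (0, 1), got {kme_min}")
    out: dict[str, list[str]] = {}
    for m in kme.columns:
        genes = modules.index[modules == m]
        if len(genes) == 0:
            warnings.warn(f"module {m!r} is empty; skipped", stacklevel=2)
            continue
        scores = kme.loc[genes, m]
        ranked = sorted(scores.index, key=lambda g: (-scores[g], g))
        if top_n is not None:
            out[m] = ranked[:top_n]
        else:
            out[m] = [g for g in ranked if scores[g] >= kme_min]
    return out


def merge_close_modules(
    expr: pd.DataFrame,
    modules: pd.Series,
    merge_corr: float = 0.75,
) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``merge_corr``.

    Single-linkage components of the eigengene correlation graph are fused,
    labels reassigned by size, and the procedure iterated until no eigengene
    pair of the resulting assignment exceeds the threshold, making the
    operation idempotent.
    """
    if not 0.0 < merge_corr < 1.0:
        raise ValueError(f"merge_corr must be in (0, 1), got {merge_corr}")
    current = modules.copy()
    for _ in range(len(modules.unique()) + 1):  # fixpoint in <= n_modules passes
        labels = [m for m in current.unique() if m != GREY]
        if len(labels) < 2:
            break
        eig = compute_eigengenes(expr, current)
        e = eig.values.loc[labels].values
        cor = np.corrcoef(e)
        adj = cor > merge_corr
        comp = _connected_components(adj)
        if all(len(c) == 1 for c in comp):
            break
        groups = []  # list of pd.Index of member genes per merged component
        for members in comp:
            member_labels = {labels[i] for i in members}
            groups.append(current.index[current.isin(member_labels)])
        groups.sort(key=lambda idx: (-len(idx), min(idx)))
        if len(groups) > len(COLOR_PALETTE):
            raise ValueError("merged module count exceeds the color palette")
        merged = pd.Series(GREY, index=current.index, dtype=object, name="module")
        for color, idx in zip(COLOR_PALETTE, groups):
            merged[idx] = color
        current = merged
    return current


def _connected_components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if adj[i, j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps
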