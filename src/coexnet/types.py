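"""Core in-memory containers shared across the pipeline stages.

Expression matrices are plain :class:`pandas.DataFrame` objects oriented
genes x samples (row index = gene IDs, columns = sample IDs); module
assignments are :class:`pandas.Series` mapping gene ID to a color label with
``"grey"`` reserved for unassigned genes. The small dataclasses here carry
everything that needs more structure than a frame: eigengene summaries, drug
signatures, and single enrichment results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EigengeneMatrix",
    "DrugSignature",
    "DrugSignatureSet",
    "EnrichmentResult",
    "GeneSetLibrary",
    "GREY",
]

#: Label reserved for genes not assigned to any module.
GREY = "grey"


@dataclass
class EigengeneMatrix:
    """Per-module summary expression profiles.

    Attributes
    ----------
    values : pandas.DataFrame
        modules x samples matrix; each row is a unit-variance eigengene
        oriented so its mean correlation with the module's genes is >= 0.
    variance_explained : pandas.Series
        Fraction of the module's (standardized) expression variance captured
        by the eigengene, per module, in [0, 1].
    """

    values: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DrugSignature:
    """Signed per-gene effect scores for one compound.

    Positive score = gene up-regulated by the drug. ``pvalues`` is optional
    and aligned to ``scores`` when present.
    """

    name: str
    scores: pd.Series
    pvalues: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].unique()
            raise ValueError(
                f"duplicate gene IDs in signature {self.name!r}: {list(dups)[:5]}"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.scores.index)

    def filter_abs(self, min_abs_score: float) -> "DrugSignature":
        """Restrict to genes with |score| >= ``min_abs_score``.

        This is the caller-side differential-expression style pre-filter used
        before overlap analyses on dense score vectors.
        """
        keep = self.scores.abs() >= min_abs_score
        return DrugSignature(
            name=self.name,
            scores=self.scores[keep],
            pvalues=self.pvalues[keep] if self.pvalues is not None else None,
        )

    def restrict(self, genes) -> "DrugSignature":
        keep = self.scores.index.intersection(pd.Index(genes))
        return DrugSignature(
            name=self.name,
            scores=self.scores.loc[keep],
            pvalues=self.pvalues.loc[keep] if self.pvalues is not None else None,
        )


@dataclass
class DrugSignatureSet:
    """An ordered panel of drug signatures, keyed by drug name."""

    signatures: dict[str, DrugSignature] = field(default_factory=dict)

    def add(self, sig: DrugSignature) -> None:
        if sig.name in self.signatures:
            raise ValueError(f"duplicate drug name {sig.name!r}")
        self.signatures[sig.name] = sig

    def __getitem__(self, name: str) -> DrugSignature:
        return self.signatures[name]

    def __iter__(self):
        return iter(self.signatures.values())

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def drugs(self) -> list[str]:
        return list(self.signatures)


@dataclass
class EnrichmentResult:
    """A 2x2 overlap test result.

    ``a`` genes in both sets, ``b`` in A only, ``c`` in B only, ``d`` in
    neither; the counts partition the universe. The odds ratio is the raw
    cross-product ratio a*d/(b*c), +inf when b*c = 0 with a*d > 0, and 0 when
    both products vanish (e.g. an empty overlap of sets covering the
    universe). ``q_value`` and ``significant`` are filled by callers that own
    the multiple-testing family and the flag rule.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None
    n_dropped: int = 0

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def flag(self, alpha: float = 0.05, or_threshold: float = 1.0) -> bool:
        """Over-representation flag: p below alpha AND odds ratio above threshold."""
        return bool(self.p_value < alpha and self.odds_ratio > or_threshold)

    def to_dict(self) -> dict:
        d = {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "significant": self.significant,
        }
        return d


class GeneSetLibrary:
    """Ordered mapping of gene-set name -> set of gene IDs, plus descriptions.

    The container behind GMT files: curated pathway libraries, cell-type
    marker collections, TF-target and kinase-substrate libraries all share
    this shape.
    """

    def __init__(self) -> None:
        self._sets: dict[str, set[str]] = {}
        self._descriptions: dict[str, str] = {}

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self._sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        genes = {str(g) for g in genes}
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if any(not g for g in genes):
            raise ValueError(f"gene set {name!r} contains an empty gene ID")
        self._sets[name] = genes
        self._descriptions[name] = description

    def __getitem__(self, name: str) -> set[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def items(self):
        return self._sets.items()

    def description(self, name: str) -> str:
        return self._descriptions[name]


def _finite_or_raise(x: float, what: str) -> float:
    if not math.isfinite(x):
        raise ValueError(f"{what} is not finite: {x!r}")
    return x
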