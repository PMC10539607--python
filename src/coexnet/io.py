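"""Readers and writers for the on-disk formats.

All tabular formats are tab-separated UTF-8 with a mandatory header row.
Missing values are an error, not a sentinel: cohort matrices are expected to
be complete after upstream filtering, and a silent NA would corrupt every
correlation downstream. Matrix round trips are lossless to 1e-12 (floats are
serialized with ``repr`` precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DrugSignature, DrugSignatureSet, GeneSetLibrary

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_drug_signatures",
    "write_drug_signatures",
    "read_table",
    "write_table",
]

#: float format used by every writer; round-trips doubles exactly.
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


def read_expression_matrix(path: str | Path, genes_in: str = "rows") -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    Parameters
    ----------
    path : path to a TSV with one header row; the first column holds gene IDs
        (``genes_in="rows"``) or sample IDs (``genes_in="columns"``).
    genes_in : {"rows", "columns"}
        Orientation of the file; the returned frame is always genes x samples.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix body")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column ID {dup!r}")
    try:
        values = df.astype(float)
    except ValueError:
        bad = _first_non_numeric(df)
        raise FormatError(
            f"{path}: non-numeric value {bad[2]!r} at row {bad[0]!r}, column {bad[1]!r}"
        ) from None
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().values)[0]
        raise FormatError(
            f"{path}: missing value at row {values.index[r]!r}, column {values.columns[c]!r}"
        )
    if genes_in == "columns":
        values = values.T
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "gene"
    return values


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.values.argmax()]
            return str(row), str(col), str(df.loc[row, col])
    return "?", "?", "?"


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene-set library: ``name TAB description TAB gene...``.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields or a repeated set name is a format error.
    """
    lib = GeneSetLibrary()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            try:
                lib.add(name, genes, description)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return lib


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in lib:
            genes = sorted(lib[name])
            fh.write("\t".join([name, lib.description(name), *genes]) + "\n")


def read_drug_signatures(path: str | Path) -> DrugSignatureSet:
    """Read a long-format signature table: columns gene, drug, score[, pvalue].

    Each (gene, drug) pair must be unique; scores must parse as finite reals.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "drug": str})
    required = {"gene", "drug", "score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        i = int(scores.isna().values.argmax())
        raise FormatError(
            f"{path}: non-numeric score {df['score'].iloc[i]!r} at data row {i + 1} "
            f"(gene {df['gene'].iloc[i]!r}, drug {df['drug'].iloc[i]!r})"
        )
    df = df.assign(score=scores)
    dup = df.duplicated(subset=["gene", "drug"])
    if dup.any():
        i = int(dup.values.argmax())
        raise FormatError(
            f"{path}: duplicate (gene, drug) pair "
            f"({df['gene'].iloc[i]!r}, {df['drug'].iloc[i]!r})"
        )
    has_p = "pvalue" in df.columns
    out = DrugSignatureSet()
    for drug, grp in df.groupby("drug", sort=False):
        scores = pd.Series(grp["score"].values, index=grp["gene"].values, name=drug)
        pvals = (
            pd.Series(pd.to_numeric(grp["pvalue"]).values, index=grp["gene"].values)
            if has_p
            else None
        )
        out.add(DrugSignature(name=str(drug), scores=scores, pvalues=pvals))
    return out


def write_drug_signatures(sigs: DrugSignatureSet, path: str | Path) -> None:
    rows = []
    for sig in sigs:
        for gene, score in sig.scores.items():
            row = {"gene": gene, "drug": sig.name, "score": score}
            if sig.pvalues is not None:
                row["pvalue"] = sig.pvalues.loc[gene]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a generic numeric TSV (covariates, signature matrices, proportions)."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed")
    if index_col is not None:
        df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
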