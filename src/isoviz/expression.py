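"""Expression matrix + metadata ingestion and normalization.

Two normalizations are provided:

* **CPM** (counts per million): per sample ``count / library_size * 1e6``,
  where library size is the sum over all transcripts present in the
  supplied matrix. Subsetting a matrix before normalizing changes the
  result, so pipelines normalize before gene filtering.
* **Relative transcript abundance**: a transcript's percent share of its
  gene's total counts within one sample.

Zero denominators (empty library, zero gene total) yield 0 rather than
NaN, with a logged warning, so downstream figures stay renderable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Long-form expression: one row per (transcript, sample).

    Columns: ``transcript_id``, ``sample_id``, ``raw_count`` and, when
    computed, ``cpm`` and ``relative_abundance`` (percent, 0-100). Group
    labels from sample metadata appear as additional columns after
    :func:`join_metadata`.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"transcript_id", "sample_id", "raw_count"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"ExpressionTable missing columns: {sorted(missing)}")
        if self.df.duplicated(subset=["transcript_id", "sample_id"]).any():
            raise ValidationError("duplicate (transcript_id, sample_id) pairs")
        if (self.df["raw_count"] < 0).any():
            raise ValidationError("negative raw counts")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def transcript_ids(self) -> set[str]:
        return set(self.df["transcript_id"].unique())

    @property
    def sample_ids(self) -> set[str]:
        return set(self.df["sample_id"].unique())

    def subset_transcripts(self, transcript_ids) -> "ExpressionTable":
        keep = set(transcript_ids)
        return ExpressionTable(
            self.df[self.df["transcript_id"].isin(keep)].reset_index(drop=True),
            dict(self.provenance),
        )


@dataclass
class SampleMetadata:
    """Sample-level grouping variables; ``sample_id`` is the unique key."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.df.columns:
            raise ValidationError("metadata needs a 'sample_id' column")
        dup = self.df["sample_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate sample IDs in metadata: "
                f"{sorted(self.df.loc[dup, 'sample_id'].unique())}"
            )

    @property
    def group_variables(self) -> list[str]:
        return [c for c in self.df.columns if c != "sample_id"]


_READERS = {
    ".tsv": lambda p, **kw: pd.read_csv(p, sep="\t", **kw),
    ".csv": lambda p, **kw: pd.read_csv(p, **kw),
    ".parquet": lambda p, **kw: pd.read_parquet(p),
    ".xlsx": lambda p, sheet_name=0, **kw: pd.read_excel(p, sheet_name=sheet_name),
}


def read_expression(
    path: str | Path,
    id_column: str = "transcript_id",
    sheet_name: str | int = 0,
) -> ExpressionTable:
    """Read a wide counts matrix (TSV/CSV/XLSX/Parquet) into long form.

    Every column other than *id_column* is treated as a numeric sample
    column. Missing cells become 0 with a logged warning; non-numeric
    cells are an error. XLSX reads the first sheet unless *sheet_name*
    says otherwise.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _READERS:
        raise FormatError(
            f"unknown expression format {suffix!r} (expected one of "
            f"{sorted(_READERS)})"
        )
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    wide = _READERS[suffix](path, sheet_name=sheet_name) if suffix == ".xlsx" else _READERS[suffix](path)
    if id_column not in wide.columns:
        raise ValidationError(f"id column {id_column!r} not in {list(wide.columns)}")
    dup = wide[id_column].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate transcript IDs: {sorted(wide.loc[dup, id_column].unique())}"
        )
    sample_cols = [c for c in wide.columns if c != id_column]
    if not sample_cols:
        raise ValidationError("expression matrix has no sample columns")
    for col in sample_cols:
        converted = pd.to_numeric(wide[col], errors="coerce")
        bad = converted.isna() & wide[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric cells in sample column {col!r}: "
                f"{wide.loc[bad, col].head(3).tolist()}"
            )
        if converted.isna().any():
            logger.warning(
                "%s: %d missing cells in sample %r treated as 0",
                path.name, int(converted.isna().sum()), col,
            )
        wide[col] = converted.fillna(0.0)
    long = wide.melt(
        id_vars=[id_column], var_name="sample_id", value_name="raw_count"
    ).rename(columns={id_column: "transcript_id"})
    long["transcript_id"] = long["transcript_id"].astype(str)
    long["sample_id"] = long["sample_id"].astype(str)
    long["raw_count"] = long["raw_count"].astype(float)
    return ExpressionTable(long, {"path": str(path), "id_column": id_column})


def read_metadata(path: str | Path, sample_column: str = "sample_id") -> SampleMetadata:
    """Read a CSV/TSV sample metadata table."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        df = pd.read_csv(path, sep="\t")
    elif suffix == ".csv":
        df = pd.read_csv(path)
    else:
        raise FormatError(f"metadata must be CSV or TSV, got {suffix!r}")
    if sample_column != "sample_id":
        df = df.rename(columns={sample_column: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df)


def join_metadata(expr: ExpressionTable, meta: SampleMetadata) -> ExpressionTable:
    """Attach group labels to every expression row.

    Every expression sample must appear in the metadata; metadata rows for
    unused samples are ignored.
    """
    missing = expr.sample_ids - set(meta.df["sample_id"])
    if missing:
        raise ValidationError(
            f"samples missing from metadata: {sorted(missing)}"
        )
    joined = expr.df.merge(meta.df, on="sample_id", how="left", validate="m:1")
    return ExpressionTable(joined, dict(expr.provenance))


def normalize_cpm(expr: ExpressionTable) -> ExpressionTable:
    """Add a ``cpm`` column: per-sample counts per million.

    The library size is the column total of the matrix in hand. Samples
    with a zero total get all-zero CPM and a warning.
    """
    df = expr.df.copy()
    totals = df.groupby("sample_id")["raw_count"].transform("sum")
    zero = totals == 0
    if zero.any():
        logger.warning(
            "samples with zero library size, CPM set to 0: %s",
            sorted(df.loc[zero, "sample_id"].unique()),
        )
    df["cpm"] = np.where(zero, 0.0, df["raw_count"] / totals.where(~zero, 1.0) * 1e6)
    return ExpressionTable(df, dict(expr.provenance))


def normalize_relative_abundance(
    expr: ExpressionTable, gene_of: Mapping[str, str]
) -> ExpressionTable:
    """Add ``relative_abundance``: percent of the gene total per sample.

    *gene_of* maps every transcript in the table to its gene. A gene with
    a zero total in some sample yields 0 for all its transcripts there.
    """
    df = expr.df.copy()
    orphans = sorted(t for t in df["transcript_id"].unique() if t not in gene_of)
    if orphans:
        raise ValidationError(f"transcripts without a gene assignment: {orphans}")
    df["_gene"] = df["transcript_id"].map(gene_of)
    totals = df.groupby(["_gene", "sample_id"])["raw_count"].transform("sum")
    zero = totals == 0
    df["relative_abundance"] = np.where(
        zero, 0.0, df["raw_count"] / totals.where(~zero, 1.0) * 100.0
    )
    df = df.drop(columns="_gene")
    return ExpressionTable(df, dict(expr.provenance))


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    """Export the long table as CSV or Parquet (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        expr.df.to_csv(path, index=False)
    elif path.suffix.lower() == ".parquet":
        expr.df.to_parquet(path, index=False)
    else:
        raise FormatError(f"export format {path.suffix!r} not supported")
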