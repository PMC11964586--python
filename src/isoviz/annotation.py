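"""GTF annotation input/output and the FeatureTable container.

Coordinates are 1-based inclusive throughout the package (the GTF
convention); interval length is therefore ``end - start + 1``. This holds
for display coordinates after gap rescaling as well, so there is a single
coordinate convention everywhere.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import GtfParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column order of a FeatureTable frame.
FEATURE_COLUMNS = [
    "seqname",
    "source",
    "feature_kind",
    "start",
    "end",
    "strand",
    "gene_id",
    "gene_name",
    "transcript_id",
    "transcript_name",
    "transcript_biotype",
    "exon_number",
]

#: Feature kinds the model understands.
KNOWN_KINDS = {"gene", "transcript", "exon", "CDS", "intron"}

#: Default kinds retained when reading a GTF.
DEFAULT_KEEP_KINDS = frozenset({"exon", "CDS"})

# Attributes extracted from column 9; anything else is ignored.
_ATTR_KEYS = ("gene_id", "gene_name", "transcript_id", "transcript_name",
              "transcript_biotype")

_QUOTED_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_BARE_ATTR = re.compile(r"(\w+)\s+([^;\s\"]+)")


@dataclass
class FeatureTable:
    """Long-form annotation records (gene/transcript/exon/CDS/intron rows).

    Wraps a pandas DataFrame with the columns in :data:`FEATURE_COLUMNS`.
    After gap rescaling, ``start``/``end`` hold display coordinates and the
    original genomic coordinates move to ``genomic_start``/``genomic_end``.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"FeatureTable frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        a = self.df[FEATURE_COLUMNS].reset_index(drop=True)
        b = other.df[FEATURE_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    @property
    def transcript_ids(self) -> set[str]:
        ids = self.df.loc[self.df["transcript_id"] != "", "transcript_id"]
        return set(ids.unique())

    def subset_kinds(self, kinds: Iterable[str]) -> "FeatureTable":
        kinds = set(kinds)
        return FeatureTable(
            self.df[self.df["feature_kind"].isin(kinds)].reset_index(drop=True),
            dict(self.provenance),
        )

    def transcript_span(self, transcript_id: str) -> tuple[int, int]:
        """(min exon start, max exon end) for one transcript.

        Transcript extent rows are optional in GTF extracts, so the span is
        always derived from the exon records.
        """
        exons = self.df[
            (self.df["transcript_id"] == transcript_id)
            & (self.df["feature_kind"] == "exon")
        ]
        if exons.empty:
            raise ValidationError(f"transcript {transcript_id!r} has no exon records")
        return int(exons["start"].min()), int(exons["end"].max())


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["exon_number"] = df["exon_number"].astype("Int64")
    for col in FEATURE_COLUMNS:
        if col in ("start", "end", "exon_number"):
            continue
        df[col] = df[col].fillna("").astype(str)
    return df


def make_feature_table(records: list[dict], provenance: dict | None = None) -> FeatureTable:
    """Build a validated FeatureTable from a list of record dicts."""
    if records:
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA if col == "exon_number" else ""
    df = _normalize_frame(df[FEATURE_COLUMNS])
    table = FeatureTable(df, provenance or {})
    validate_features(table)
    return table


def validate_features(table: FeatureTable) -> None:
    """Enforce the FeatureTable invariants; raises ValidationError."""
    df = table.df
    bad = df[df["start"] > df["end"]]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValidationError(
            f"start > end for {r['feature_kind']} ({r['start']}, {r['end']}) "
            f"of transcript {r['transcript_id']!r}"
        )
    bad_strand = df[~df["strand"].isin(["+", "-"])]
    if not bad_strand.empty:
        raise ValidationError(
            f"strand must be '+' or '-', got {sorted(bad_strand['strand'].unique())}; "
            "records with '.' or '?' strand are rejected because exon numbering "
            "and intron arrows are strand-dependent"
        )
    core = df[df["feature_kind"].isin(["exon", "CDS"])]
    if (core["transcript_id"] == "").any() or (core["gene_id"] == "").any():
        raise ValidationError("exon/CDS records must carry transcript_id and gene_id")
    # one seqname + one strand per transcript
    with_tx = df[df["transcript_id"] != ""]
    if not with_tx.empty:
        nun = with_tx.groupby("transcript_id")[["seqname", "strand"]].nunique()
        mixed = nun[(nun["seqname"] > 1) | (nun["strand"] > 1)]
        if not mixed.empty:
            raise ValidationError(
                f"transcripts on multiple seqnames/strands: {list(mixed.index[:5])}"
            )
    # CDS-bearing transcripts must also have exons
    cds_tx = set(df.loc[df["feature_kind"] == "CDS", "transcript_id"])
    exon_tx = set(df.loc[df["feature_kind"] == "exon", "transcript_id"])
    orphan_cds = cds_tx - exon_tx
    if orphan_cds:
        raise ValidationError(
            f"transcripts with CDS but no exon records: {sorted(orphan_cds)[:5]}"
        )


def _parse_attributes(attr_field: str, lenient: bool) -> dict:
    attrs = dict(_QUOTED_ATTR.findall(attr_field))
    if lenient:
        # Unquoted `key value;` pairs (RefSeq-style dialects).
        for key, value in _BARE_ATTR.findall(attr_field):
            attrs.setdefault(key, value)
    return {k: attrs.get(k, "") for k in _ATTR_KEYS}


def read_gtf(
    path: str | Path,
    keep_kinds: Iterable[str] | None = None,
    lenient_attributes: bool = True,
) -> FeatureTable:
    """Parse a GTF file into a FeatureTable.

    Only records whose feature kind is in *keep_kinds* (default
    ``{exon, CDS}``) are retained, in file order. Missing ``gene_name``
    falls back to ``gene_id`` and missing ``transcript_name`` to
    ``transcript_id`` so display labels are never empty. Duplicate
    identical records are dropped with a warning.

    Parameters
    ----------
    path
        GTF file (tab-separated, 9 columns, ``key "value";`` attributes,
        ``#`` comment lines).
    keep_kinds
        Feature kinds to retain.
    lenient_attributes
        Also accept unquoted ``key value;`` attribute pairs.
    """
    path = Path(path)
    keep = set(keep_kinds) if keep_kinds is not None else set(DEFAULT_KEEP_KINDS)
    records: list[dict] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqname, source, kind, start_s, end_s, _score, strand, _frame, attr = fields
            if kind not in keep:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path.name}:{lineno}: strand {strand!r} not supported; "
                    "features need an explicit '+' or '-' strand"
                )
            attrs = _parse_attributes(attr, lenient_attributes)
            if kind in ("exon", "CDS", "transcript", "intron") and not attrs["transcript_id"]:
                raise ValidationError(
                    f"{path.name}:{lineno}: {kind} record lacks transcript_id"
                )
            if not attrs["gene_name"]:
                attrs["gene_name"] = attrs["gene_id"]
            if not attrs["transcript_name"]:
                attrs["transcript_name"] = attrs["transcript_id"]
            en = None
            m = re.search(r'exon_number\s+"?(\d+)"?', attr)
            if m:
                en = int(m.group(1))
            records.append(
                dict(
                    seqname=seqname,
                    source=source,
                    feature_kind=kind,
                    start=start,
                    end=end,
                    strand=strand,
                    exon_number=en,
                    **attrs,
                )
            )
    if not records:
        raise ValidationError(
            f"{path.name}: no features retained (kept kinds: {sorted(keep)})"
        )
    df = pd.DataFrame.from_records(records)
    dup = df.duplicated(subset=["transcript_id", "feature_kind", "start", "end"])
    if dup.any():
        logger.warning("%s: dropped %d duplicate records", path.name, int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    df["exon_number"] = df["exon_number"].astype("Int64")
    table = FeatureTable(
        _normalize_frame(df[FEATURE_COLUMNS]),
        {"path": str(path), "keep_kinds": sorted(keep), "lenient": lenient_attributes},
    )
    validate_features(table)
    return table


def write_gtf(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as a 9-column GTF file.

    Attributes are serialized as ``key "value";`` in a fixed key order;
    empty optional attributes are omitted rather than written as empty
    strings, so ``read_gtf(write_gtf(t)) == t``.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty FeatureTable")
    path = Path(path)
    lines = []
    for row in table.df.itertuples(index=False):
        parts = []
        for key in _ATTR_KEYS:
            value = getattr(row, key)
            if value:
                parts.append(f'{key} "{value}";')
        if pd.notna(row.exon_number):
            parts.append(f'exon_number "{int(row.exon_number)}";')
        lines.append(
            "\t".join(
                [
                    row.seqname,
                    row.source or ".",
                    row.feature_kind,
                    str(int(row.start)),
                    str(int(row.end)),
                    ".",
                    row.strand,
                    ".",
                    " ".join(parts),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ConsistencyReport:
    """Transcript-ID overlap between an annotation and an expression table."""

    shared: frozenset[str]
    annotation_only: frozenset[str]
    expression_only: frozenset[str]


def check_expression_consistency(table: FeatureTable, expr) -> ConsistencyReport:
    """Report shared / annotation-only / expression-only transcript IDs.

    A pure report: the caller decides whether a mismatch is an error.
    """
    ann_ids = table.transcript_ids
    expr_ids = set(expr.df["transcript_id"].unique())
    return ConsistencyReport(
        shared=frozenset(ann_ids & expr_ids),
        annotation_only=frozenset(ann_ids - expr_ids),
        expression_only=frozenset(expr_ids - ann_ids),
    )
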