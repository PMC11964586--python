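"""Gene filtering, isoform selection, exon numbering, intron derivation
and the shared long-intron rescaling map.

The rescaling model: the union of exon intervals across *all* displayed
transcripts is kept at genomic scale; every uncovered gap inside the locus
is compressed to at most ``cap`` display units (uniformly within the gap).
Because the map is shared, all transcripts of a gene stay mutually aligned
on one display axis, and exon/CDS lengths are preserved exactly.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureTable
from .errors import ConfigurationError, ValidationError
from .expression import ExpressionTable

logger = logging.getLogger(__name__)

VALID_METRICS = ("raw_count", "cpm", "relative_abundance")
REDUCERS = {"mean": "mean", "median": "median", "sum": "sum"}


# ---------------------------------------------------------------------------
# gene filtering and ranking
# ---------------------------------------------------------------------------

def filter_gene(
    annotation: FeatureTable,
    expr: ExpressionTable | None,
    gene: str,
    case_insensitive: bool = False,
) -> tuple[FeatureTable, ExpressionTable | None]:
    """Restrict annotation (and expression) to one gene.

    *gene* is matched exactly against ``gene_id`` or ``gene_name``
    (case-insensitively behind the flag). The returned expression table is
    restricted to transcripts present in the filtered annotation.
    """
    df = annotation.df
    if case_insensitive:
        g = gene.lower()
        mask = (df["gene_id"].str.lower() == g) | (df["gene_name"].str.lower() == g)
    else:
        mask = (df["gene_id"] == gene) | (df["gene_name"] == gene)
    if not mask.any():
        prefix = gene[: max(3, len(gene) // 2)]
        near = sorted(
            set(df.loc[df["gene_id"].str.startswith(prefix), "gene_id"])
            | set(df.loc[df["gene_name"].str.startswith(prefix), "gene_name"])
        )[:5]
        hint = f"; near matches: {near}" if near else ""
        raise ValidationError(f"gene {gene!r} not found in annotation{hint}")
    ann = FeatureTable(df[mask].reset_index(drop=True), dict(annotation.provenance))
    if expr is None:
        return ann, None
    return ann, expr.subset_transcripts(ann.transcript_ids)


def rank_and_select(
    expr: ExpressionTable,
    metric: str = "raw_count",
    reducer: str = "mean",
    top_n: int = 5,
) -> list[str]:
    """Order transcripts by reduced expression, descending; return top_n.

    Ties break lexicographically on transcript_id (ascending). Asking for
    more transcripts than exist returns all of them with a warning.
    """
    if metric not in VALID_METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; use one of {VALID_METRICS}")
    if reducer not in REDUCERS:
        raise ConfigurationError(f"unknown reducer {reducer!r}; use one of {sorted(REDUCERS)}")
    if metric not in expr.df.columns:
        raise ConfigurationError(f"metric {metric!r} not computed on this table")
    if top_n < 1:
        raise ConfigurationError("top_n must be a positive integer")
    agg = (
        expr.df.groupby("transcript_id")[metric]
        .agg(REDUCERS[reducer])
        .reset_index()
        .sort_values([metric, "transcript_id"], ascending=[False, True])
    )
    ids = agg["transcript_id"].tolist()
    if top_n > len(ids):
        logger.warning("top_n=%d exceeds %d available transcripts", top_n, len(ids))
    return ids[:top_n]


# ---------------------------------------------------------------------------
# exon numbering and intron derivation
# ---------------------------------------------------------------------------

def add_exon_number(annotation: FeatureTable) -> FeatureTable:
    """Number exons 1..n per transcript in transcription order.

    '+' strand: ascending genomic start; '-' strand: descending. CDS
    records inherit the number of the exon that contains them.
    """
    df = annotation.df.copy()
    numbers = pd.Series(pd.NA, index=df.index, dtype="Int64")
    for tx, sub in df[df["feature_kind"] == "exon"].groupby("transcript_id"):
        strand = sub["strand"].iloc[0]
        order = sub.sort_values("start", ascending=(strand == "+"))
        numbers.loc[order.index] = np.arange(1, len(order) + 1)
        # CDS containment lookup within this transcript
        cds = df[(df["transcript_id"] == tx) & (df["feature_kind"] == "CDS")]
        for idx, row in cds.iterrows():
            hit = order[(order["start"] <= row["start"]) & (order["end"] >= row["end"])]
            if hit.empty:
                raise ValidationError(
                    f"CDS ({row['start']}, {row['end']}) of transcript {tx!r} "
                    "is not contained in any exon"
                )
            numbers.loc[idx] = numbers.loc[hit.index[0]]
    df["exon_number"] = numbers
    return FeatureTable(df, dict(annotation.provenance))


def to_intron(annotation: FeatureTable) -> FeatureTable:
    """Append intron records derived from each transcript's exons.

    For consecutive exons (sorted by start) the intron is
    ``(prev.end + 1, next.start - 1)``; adjacent exons produce none.
    Overlapping exons within a transcript are an error.
    """
    df = annotation.df
    new_rows: list[dict] = []
    for tx, sub in df[df["feature_kind"] == "exon"].groupby("transcript_id", sort=False):
        sub = sub.sort_values("start")
        prev_end = None
        template = sub.iloc[0]
        for _, exon in sub.iterrows():
            if prev_end is not None:
                if exon["start"] <= prev_end:
                    raise ValidationError(
                        f"overlapping exons in transcript {tx!r} "
                        f"(exon starting {exon['start']} overlaps previous end {prev_end})"
                    )
                if exon["start"] > prev_end + 1:
                    new_rows.append(
                        dict(
                            seqname=template["seqname"],
                            source=template["source"],
                            feature_kind="intron",
                            start=int(prev_end + 1),
                            end=int(exon["start"] - 1),
                            strand=template["strand"],
                            gene_id=template["gene_id"],
                            gene_name=template["gene_name"],
                            transcript_id=tx,
                            transcript_name=template["transcript_name"],
                            transcript_biotype=template["transcript_biotype"],
                            exon_number=pd.NA,
                        )
                    )
            prev_end = exon["end"]
    if new_rows:
        introns = pd.DataFrame.from_records(new_rows)
        introns["exon_number"] = introns["exon_number"].astype("Int64")
        out = pd.concat([df, introns[df.columns]], ignore_index=True)
    else:
        out = df.copy()
    return FeatureTable(out, dict(annotation.provenance))


# ---------------------------------------------------------------------------
# gap map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One piece of the piecewise-linear genomic→display map."""

    genomic_start: int
    genomic_end: int
    display_start: float
    display_end: float
    covered: bool

    @property
    def genomic_length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    @property
    def display_length(self) -> float:
        return self.display_end - self.display_start + 1


@dataclass(frozen=True)
class GapMap:
    """Strictly increasing genomic→display mapping for one locus.

    Covered (exon-union) segments keep genomic scale; uncovered gaps are
    compressed uniformly so their display length is ``min(length, cap)``.
    Display coordinates stay 1-based inclusive; the display start of a
    feature at genomic position *s* is the cumulative display length
    through ``s - 1`` plus one, and its display end is the cumulative
    display length through its genomic end. Exon boundaries therefore map
    to integers whenever cap is an integer.
    """

    segments: tuple[Segment, ...]
    cap: float

    @property
    def genomic_domain(self) -> tuple[int, int]:
        return self.segments[0].genomic_start, self.segments[-1].genomic_end

    def _segment_for(self, pos: int) -> Segment:
        lo, hi = self.genomic_domain
        if not (lo <= pos <= hi):
            raise ValidationError(
                f"position {pos} outside map domain [{lo}, {hi}]"
            )
        starts = [s.genomic_start for s in self.segments]
        return self.segments[bisect_right(starts, pos) - 1]

    def _cumulative(self, pos: int) -> float:
        """Display length accumulated through genomic base *pos*."""
        seg = self._segment_for(pos)
        frac = (pos - seg.genomic_start + 1) / seg.genomic_length
        return (seg.display_start - 1) + frac * seg.display_length

    def display_start_of(self, genomic_start: int) -> float:
        lo = self.genomic_domain[0]
        if genomic_start == lo:
            return 1.0
        return self._cumulative(genomic_start - 1) + 1.0

    def display_end_of(self, genomic_end: int) -> float:
        return self._cumulative(genomic_end)


def _union_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_gap_map(
    annotation: FeatureTable,
    cap: float = 100.0,
    transcripts: Iterable[str] | None = None,
) -> GapMap:
    """Build the shared rescaling map for one locus.

    Uses the union of exon intervals across the displayed transcripts (all
    transcripts when *transcripts* is None). The annotation must sit on a
    single seqname.
    """
    if cap <= 0:
        raise ConfigurationError(f"cap must be positive, got {cap}")
    df = annotation.df
    if transcripts is not None:
        keep = set(transcripts)
        df = df[df["transcript_id"].isin(keep)]
    exons = df[df["feature_kind"] == "exon"]
    if exons.empty:
        raise ValidationError("no exon records among the displayed transcripts")
    if df["seqname"].nunique() > 1:
        raise ValidationError(
            f"locus spans multiple seqnames: {sorted(df['seqname'].unique())}"
        )
    covered = _union_intervals(list(zip(exons["start"], exons["end"])))
    segments: list[Segment] = []
    disp = 0.0  # cumulative display length so far
    prev_end: int | None = None
    for s, e in covered:
        if prev_end is not None and s > prev_end + 1:
            gap_len = s - 1 - (prev_end + 1) + 1
            d_len = min(float(gap_len), float(cap))
            segments.append(
                Segment(prev_end + 1, s - 1, disp + 1, disp + d_len, covered=False)
            )
            disp += d_len
        g_len = e - s + 1
        segments.append(Segment(s, e, disp + 1, disp + g_len, covered=True))
        disp += g_len
        prev_end = e
    return GapMap(tuple(segments), float(cap))


def apply_gap_map(gap_map: GapMap, annotation: FeatureTable) -> FeatureTable:
    """Rewrite record coordinates into display space.

    Genomic coordinates are preserved in ``genomic_start``/``genomic_end``
    columns (hover payloads and lengths always report genomic values).
    Exon and CDS display lengths equal their genomic lengths; intron
    display lengths are at most their genomic lengths.
    """
    df = annotation.df.copy()
    lo, hi = gap_map.genomic_domain
    out_of_domain = df[(df["start"] < lo) | (df["end"] > hi)]
    if not out_of_domain.empty:
        r = out_of_domain.iloc[0]
        raise ValidationError(
            f"record ({r['start']}, {r['end']}) of transcript "
            f"{r['transcript_id']!r} outside map domain [{lo}, {hi}]"
        )
    df["genomic_start"] = df["start"]
    df["genomic_end"] = df["end"]
    df["start"] = [gap_map.display_start_of(int(s)) for s in df["genomic_start"]]
    df["end"] = [gap_map.display_end_of(int(e)) for e in df["genomic_end"]]
    return FeatureTable(df, dict(annotation.provenance))
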