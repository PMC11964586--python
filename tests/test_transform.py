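"""Gene filtering, ranking, exon numbering, introns and the gap map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import BruteForceMap, merge_intervals, random_locus
from isoviz import (
    ConfigurationError,
    ExpressionTable,
    ValidationError,
    add_exon_number,
    apply_gap_map,
    build_gap_map,
    filter_gene,
    make_feature_table,
    rank_and_select,
    to_intron,
)


def _exon_table(exons, strand="+", tx="T1", gene="G1", cds=()):
    rows = []
    for s, e in exons:
        rows.append(dict(seqname="chr1", source="t", feature_kind="exon",
                         start=s, end=e, strand=strand, gene_id=gene,
                         gene_name=gene, transcript_id=tx, transcript_name=tx,
                         transcript_biotype="", exon_number=None))
    for s, e in cds:
        rows.append(dict(rows[0], feature_kind="CDS", start=s, end=e))
    return rows


# ---------------------------------------------------------------------------
# filter_gene / rank_and_select
# ---------------------------------------------------------------------------

def test_filter_gene_by_id_and_symbol_agree(dataset):
    ann, wide, _, truth = dataset
    long = wide.melt("transcript_id", var_name="sample_id", value_name="raw_count")
    expr = ExpressionTable(long)
    gene = truth.focal_gene
    symbol = ann.df.loc[ann.df["gene_id"] == gene, "gene_name"].iloc[0]
    by_id, expr_id = filter_gene(ann, expr, gene)
    by_symbol, expr_sym = filter_gene(ann, expr, symbol)
    assert by_id == by_symbol
    assert expr_id.transcript_ids == expr_sym.transcript_ids == set(
        truth.transcripts_of[gene])


def test_filter_gene_no_match_lists_near_matches(dataset):
    ann, _, _, _ = dataset
    with pytest.raises(ValidationError, match="SIMG"):
        filter_gene(ann, None, "SIMG99999")
    # case-insensitive flag rescues a lowercase query
    table, _ = filter_gene(ann, None, "gene1", case_insensitive=True)
    assert set(table.df["gene_name"]) == {"GENE1"}


def test_rank_and_select_ordering_and_ties():
    long = pd.DataFrame({
        "transcript_id": ["T1", "T2", "T3", "T1", "T2", "T3"],
        "sample_id": ["a"] * 3 + ["b"] * 3,
        "raw_count": [10.0, 30.0, 20.0, 10.0, 30.0, 20.0],
    })
    expr = ExpressionTable(long)
    assert rank_and_select(expr, "raw_count", "mean", 2) == ["T2", "T3"]
    tie = ExpressionTable(pd.DataFrame({
        "transcript_id": ["T2", "T1"], "sample_id": ["a", "a"],
        "raw_count": [5.0, 5.0]}))
    assert rank_and_select(tie, "raw_count", "mean", 2) == ["T1", "T2"]
    with pytest.raises(ConfigurationError):
        rank_and_select(expr, "tpm", "mean", 1)
    with pytest.raises(ConfigurationError):
        rank_and_select(expr, "raw_count", "max", 1)


def test_rank_matches_generator_bookkeeping(dataset, caplog):
    ann, wide, _, truth = dataset
    gene = truth.focal_gene
    txs = truth.transcripts_of[gene]
    long = wide[wide["transcript_id"].isin(txs)].melt(
        "transcript_id", var_name="sample_id", value_name="raw_count")
    expr = ExpressionTable(long)
    assert rank_and_select(expr, "raw_count", "mean", 5) == \
        truth.rank_by_mean_count[gene][:5]
    with caplog.at_level("WARNING"):
        everything = rank_and_select(expr, "raw_count", "mean", 999)
    assert everything == truth.rank_by_mean_count[gene]
    assert "exceeds" in caplog.text


# ---------------------------------------------------------------------------
# exon numbering
# ---------------------------------------------------------------------------

def test_exon_numbering_follows_transcription_order():
    plus = make_feature_table(_exon_table([(100, 200), (300, 400)], "+"))
    out = add_exon_number(plus)
    assert list(out.df.sort_values("start")["exon_number"]) == [1, 2]
    minus = make_feature_table(_exon_table([(100, 200), (300, 400)], "-"))
    out = add_exon_number(minus)
    assert list(out.df.sort_values("start")["exon_number"]) == [2, 1]


def test_cds_inherits_containing_exon_number():
    table = make_feature_table(
        _exon_table([(100, 200), (300, 400)], "-", cds=[(320, 380)]))
    out = add_exon_number(table)
    cds = out.df[out.df["feature_kind"] == "CDS"]
    assert list(cds["exon_number"]) == [1]  # (300,400) is exon 1 on '-'
    dangling = make_feature_table(
        _exon_table([(100, 200)], "+", cds=[(150, 250)]))
    with pytest.raises(ValidationError, match="not contained"):
        add_exon_number(dangling)


def test_strand_flip_reverses_numbering(dataset):
    """Involution: flipping a transcript's strand reverses its numbering."""
    ann, _, _, truth = dataset
    clean = set(ann.transcript_ids) - {
        t for g in truth.faulty_genes for t in truth.transcripts_of[g]}
    numbered = add_exon_number(ann)
    flipped_df = ann.df.copy()
    flipped_df["strand"] = flipped_df["strand"].map({"+": "-", "-": "+"})
    flipped = add_exon_number(make_feature_table(flipped_df.to_dict("records")))
    for tx in clean:
        a = numbered.df[(numbered.df["transcript_id"] == tx)
                        & (numbered.df["feature_kind"] == "exon")].sort_values("start")
        b = flipped.df[(flipped.df["transcript_id"] == tx)
                       & (flipped.df["feature_kind"] == "exon")].sort_values("start")
        n = len(a)
        assert list(a["exon_number"] + b["exon_number"].values) == [n + 1] * n


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

def test_intron_derivation_basic_cases():
    table = make_feature_table(_exon_table([(100, 200), (300, 400), (500, 600)]))
    out = to_intron(table)
    introns = out.df[out.df["feature_kind"] == "intron"]
    assert list(zip(introns["start"], introns["end"])) == [(201, 299), (401, 499)]
    single = make_feature_table(_exon_table([(100, 200)]))
    assert (to_intron(single).df["feature_kind"] == "intron").sum() == 0
    adjacent = make_feature_table(_exon_table([(100, 200), (201, 300)]))
    assert (to_intron(adjacent).df["feature_kind"] == "intron").sum() == 0


def test_overlapping_exons_rejected():
    table = make_feature_table(_exon_table([(100, 200), (150, 300)]))
    with pytest.raises(ValidationError, match="T1"):
        to_intron(table)


def test_intron_tiling_on_fixture(dataset):
    """Per transcript: exon lengths + intron lengths == span length."""
    ann, _, _, truth = dataset
    out = to_intron(ann)
    for tx in ann.transcript_ids:
        sub = out.df[out.df["transcript_id"] == tx]
        exons = sub[sub["feature_kind"] == "exon"]
        introns = sub[sub["feature_kind"] == "intron"]
        span = exons["end"].max() - exons["start"].min() + 1
        total = ((exons["end"] - exons["start"] + 1).sum()
                 + (introns["end"] - introns["start"] + 1).sum())
        assert total == span
        assert truth.introns[tx] == [[int(s), int(e)] for s, e
                                     in zip(introns["start"], introns["end"])]


# ---------------------------------------------------------------------------
# gap map
# ---------------------------------------------------------------------------

def test_gap_map_two_exon_example():
    table = make_feature_table(_exon_table([(1, 100), (10001, 10100)]))
    gm = build_gap_map(table, cap=100)
    out = apply_gap_map(gm, to_intron(table))
    exons = out.df[out.df["feature_kind"] == "exon"].sort_values("genomic_start")
    assert list(zip(exons["start"], exons["end"])) == [(1.0, 100.0), (201.0, 300.0)]
    intron = out.df[out.df["feature_kind"] == "intron"].iloc[0]
    assert intron["end"] - intron["start"] + 1 == 100.0  # exactly the cap


def test_gap_below_cap_is_identity():
    table = make_feature_table(_exon_table([(1, 100), (150, 250)]))
    gm = build_gap_map(table, cap=100)
    out = apply_gap_map(gm, table)
    assert (out.df["start"] == out.df["genomic_start"]).all()
    assert (out.df["end"] == out.df["genomic_end"]).all()


def test_union_covers_exon_inside_other_transcripts_intron():
    rows = _exon_table([(1, 100), (10001, 10100)], tx="T1")
    rows += _exon_table([(5001, 5100)], tx="T2")
    table = make_feature_table(rows)
    gm = build_gap_map(table, cap=100)
    oracle = BruteForceMap([(1, 100), (5001, 5100), (10001, 10100)], 100)
    for pos in (1, 100, 5001, 5100, 10001, 10100):
        assert gm.display_start_of(pos) == oracle.display_start_of(pos)
        assert gm.display_end_of(pos) == oracle.display_end_of(pos)
    # the two sub-gaps are capped independently: 100 + 100 + 100 + 100 + 100
    assert gm.display_end_of(10100) == 500.0


def test_gap_map_matches_bruteforce_on_random_loci():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        exons = random_locus(rng)
        rows = []
        for i, (s, e) in enumerate(exons):
            rows += _exon_table([(s, e)], tx=f"T{i}")
        table = make_feature_table(rows)
        cap = float(rng.integers(10, 500))
        gm = build_gap_map(table, cap=cap)
        oracle = BruteForceMap(exons, cap)
        for s, e in merge_intervals(exons):
            assert gm.display_start_of(s) == pytest.approx(oracle.display_start_of(s), abs=1e-6)
            assert gm.display_end_of(e) == pytest.approx(oracle.display_end_of(e), abs=1e-6)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_gap_map_monotonic_and_length_preserving(seed):
    rng = np.random.default_rng(seed)
    exons = random_locus(rng)
    rows = []
    for i, (s, e) in enumerate(exons):
        rows += _exon_table([(s, e)], tx=f"T{i}")
    table = make_feature_table(rows)
    gm = build_gap_map(table, cap=100)
    out = apply_gap_map(gm, table)
    ex = out.df[out.df["feature_kind"] == "exon"]
    # exon display length == genomic length, always
    assert np.allclose(ex["end"] - ex["start"],
                       ex["genomic_end"] - ex["genomic_start"])
    # strictly increasing across a sweep of in-exon positions
    positions = sorted(set(int(p) for s, e in exons for p in (s, e, (s + e) // 2)))
    displayed = [gm.display_end_of(p) for p in positions]
    assert all(a < b for a, b in zip(displayed, displayed[1:]))


def test_gap_map_idempotent_after_first_application():
    table = make_feature_table(_exon_table([(1, 100), (10001, 10100)]))
    once = apply_gap_map(build_gap_map(table, cap=100), table)
    redo_input = make_feature_table(
        once.df.assign(start=once.df["start"].astype(int),
                       end=once.df["end"].astype(int))
        [ [c for c in table.df.columns] ].to_dict("records"))
    twice = apply_gap_map(build_gap_map(redo_input, cap=100), redo_input)
    assert (twice.df["start"] == twice.df["genomic_start"]).all()


def test_gap_map_errors():
    table = make_feature_table(_exon_table([(1, 100)]))
    with pytest.raises(ConfigurationError):
        build_gap_map(table, cap=0)
    mixed = _exon_table([(1, 100)], tx="T1")
    other = _exon_table([(1, 100)], tx="T2")
    for r in other:
        r["seqname"] = "chr2"
    with pytest.raises(ValidationError, match="seqname"):
        build_gap_map(make_feature_table(mixed + other), cap=100)
    gm = build_gap_map(table, cap=100)
    outside = make_feature_table(_exon_table([(1, 200)]))
    with pytest.raises(ValidationError, match="outside map domain"):
        apply_gap_map(gm, outside)


def test_gap_map_truth_segments_match(dataset):
    """Generator's expected breakpoints equal the built map's segments."""
    ann, _, _, truth = dataset
    for gene, segs in truth.gap_segments.items():
        if gene in truth.faulty_genes:
            continue
        sub = ann.df[ann.df["gene_id"] == gene]
        from isoviz.annotation import FeatureTable
        gm = build_gap_map(FeatureTable(sub.reset_index(drop=True)),
                           cap=truth.config["rescale_cap"])
        built = [[s.genomic_start, s.genomic_end, s.display_start, s.display_end]
                 for s in gm.segments]
        assert built == segs
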