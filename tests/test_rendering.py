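"""Box statistics, figure assembly and HTML/SVG export."""

import numpy as np
import pandas as pd
import pytest

from _oracles import tukey_box
from isoviz import (
    AssemblyError,
    ConfigurationError,
    ExpressionTable,
    assemble_figure,
    compute_box_stats,
    export_html,
    export_static,
    make_expression_panel,
    make_feature_table,
    make_structure_panel,
    render_svg,
)
from isoviz.rendering import CDS_HEIGHT_FRAC, EXON_HEIGHT_FRAC


def _expr(values_by_cell):
    rows = []
    for (tx, grp), values in values_by_cell.items():
        for i, v in enumerate(values):
            rows.append({"transcript_id": tx, "sample_id": f"{grp}{i}",
                         "raw_count": float(v), "condition": grp})
    return ExpressionTable(pd.DataFrame(rows))


def _structure_table(cds=True, strand="+"):
    rows = [
        dict(seqname="chr1", source="t", feature_kind="exon", start=s, end=e,
             strand=strand, gene_id="G1", gene_name="G1", transcript_id="T1",
             transcript_name="T1-201", transcript_biotype="", exon_number=n)
        for (s, e), n in [((100, 200), 1), ((300, 400), 2)]
    ]
    rows.append(dict(rows[0], feature_kind="intron", start=201, end=299,
                     exon_number=None))
    if cds:
        rows.append(dict(rows[0], feature_kind="CDS", start=150, end=200))
    return make_feature_table(rows)


# ---------------------------------------------------------------------------
# box statistics
# ---------------------------------------------------------------------------

def test_box_stats_hand_computed_example():
    """[1,2,3,4,100]: Q1=2, median=3, Q3=4, upper fence 7, outlier 100."""
    expr = _expr({("T1", "g"): [1, 2, 3, 4, 100]})
    (b,) = compute_box_stats(expr, "raw_count", ["T1"], "condition")
    assert b.median == 3 and b.lower_quartile == 2 and b.upper_quartile == 4
    assert b.iqr == 2
    assert b.whisker_high == 4  # most extreme point within Q3 + 1.5*IQR = 7
    assert b.whisker_low == 1
    assert b.outliers == (100.0,)
    assert sorted(b.points) == [1, 2, 3, 4, 100]


def test_box_stats_constant_values():
    expr = _expr({("T1", "g"): [5, 5, 5, 5]})
    (b,) = compute_box_stats(expr, "raw_count", ["T1"], "condition")
    assert b.median == b.lower_quartile == b.upper_quartile == 5
    assert b.outliers == ()
    assert b.whisker_low == b.whisker_high == 5


def test_box_stats_matches_bruteforce_on_random_samples():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(3, 51))
        values = np.round(rng.exponential(10, n) + rng.uniform(0, 5, n), 3)
        expr = _expr({("T1", "g"): values})
        (b,) = compute_box_stats(expr, "raw_count", ["T1"], "condition")
        ref = tukey_box(values.tolist())
        assert b.median == pytest.approx(ref["median"], abs=1e-12)
        assert b.lower_quartile == pytest.approx(ref["q1"], abs=1e-12)
        assert b.upper_quartile == pytest.approx(ref["q3"], abs=1e-12)
        assert b.whisker_low == ref["whisker_low"]
        assert b.whisker_high == ref["whisker_high"]
        assert list(b.outliers) == ref["outliers"]
        # cross-check against numpy's own linear-interpolation percentiles
        assert np.percentile(values, [25, 50, 75]) == pytest.approx(
            [b.lower_quartile, b.median, b.upper_quartile], rel=1e-12)


def test_box_stats_four_points_per_group_and_empty_group(caplog):
    expr = _expr({("T1", "AD"): [1, 2, 3, 4], ("T1", "control"): [5, 6, 7, 8],
                  ("T2", "AD"): [1, 1, 2, 2]})
    boxes = compute_box_stats(expr, "raw_count", ["T1", "T2"], "condition")
    assert [b.n for b in boxes[:3]] == [4, 4, 4]
    with caplog.at_level("WARNING"):
        boxes = compute_box_stats(expr, "raw_count", ["T2"], "condition")
    empty = [b for b in boxes if b.group == "control"][0]
    assert empty.n == 0 and "no raw_count values" in caplog.text
    with pytest.raises(ConfigurationError):
        compute_box_stats(expr, "raw_count", ["T1"], "batch")


# ---------------------------------------------------------------------------
# structure panel
# ---------------------------------------------------------------------------

def test_structure_panel_heights_and_hover():
    panel = make_structure_panel(_structure_table(), ["T1"])
    exons = [s for s in panel.shapes if s.kind == "exon"]
    cds = [s for s in panel.shapes if s.kind == "cds"]
    assert all(s.height == EXON_HEIGHT_FRAC for s in exons)
    assert all(s.height == CDS_HEIGHT_FRAC for s in cds)
    assert CDS_HEIGHT_FRAC == 2 * EXON_HEIGHT_FRAC
    hover = exons[0].hover
    assert hover == {"start": 100, "end": 200, "length": 101, "exon_number": 1,
                     "chromosome": "chr1", "transcript": "T1"}


def test_hover_length_uses_genomic_not_display_coordinates():
    from isoviz import apply_gap_map, build_gap_map, to_intron

    rows = [
        dict(seqname="chr1", source="t", feature_kind="exon", start=s, end=e,
             strand="+", gene_id="G1", gene_name="G1", transcript_id="T1",
             transcript_name="T1", transcript_biotype="", exon_number=i + 1)
        for i, (s, e) in enumerate([(1, 100), (10001, 10100)])
    ]
    table = make_feature_table(rows)
    display = apply_gap_map(build_gap_map(table, cap=100), to_intron(table))
    panel = make_structure_panel(display, ["T1"])
    intron = [s for s in panel.shapes if s.kind == "intron"][0]
    assert intron.hover["length"] == 9900  # genomic, though display span is 100
    assert intron.x1 - intron.x0 + 1 == 100


def test_noncoding_transcript_renders_all_boxes_short():
    panel = make_structure_panel(_structure_table(cds=False), ["T1"])
    kinds = {s.kind for s in panel.shapes}
    assert "cds" not in kinds
    assert all(s.height == EXON_HEIGHT_FRAC for s in panel.shapes if s.kind == "exon")


@pytest.mark.parametrize("strand, expect_cls", [("+", "strand-plus"), ("-", "strand-minus")])
def test_intron_arrows_follow_strand(strand, expect_cls):
    table = _structure_table(strand=strand)
    panel = make_structure_panel(table, ["T1"], arrow_spacing=30.0)
    arrows = [s for s in panel.shapes if s.kind == "arrow"]
    assert arrows and all(a.strand == strand for a in arrows)
    svg = render_svg(assemble_figure(panel))
    assert expect_cls in svg


def test_missing_transcript_raises_assembly_error():
    with pytest.raises(AssemblyError, match="T9"):
        make_structure_panel(_structure_table(), ["T1", "T9"])


# ---------------------------------------------------------------------------
# assembly and export
# ---------------------------------------------------------------------------

def _figure(seed=0):
    table = _structure_table()
    expr = _expr({("T1", "AD"): [1, 2, 3, 4], ("T1", "control"): [2, 4, 6, 8]})
    structure = make_structure_panel(table, ["T1"])
    panel = make_expression_panel(expr, "raw_count", ["T1"], "condition", seed=seed)
    return assemble_figure(structure, [panel], ["T1"], title="G1", jitter_seed=seed)


def test_structure_only_assembly_is_valid():
    fig = assemble_figure(make_structure_panel(_structure_table(), ["T1"]))
    assert fig.row_order == ("T1",)
    assert fig.expression_panels == ()
    assert render_svg(fig).startswith("<svg")


def test_row_order_mismatch_rejected():
    structure = make_structure_panel(_structure_table(), ["T1"])
    expr = _expr({("T1", "AD"): [1, 2]})
    panel = make_expression_panel(expr, "raw_count", ["T1"], "condition")
    with pytest.raises(AssemblyError):
        assemble_figure(structure, [panel], ["T1", "T2"])


def test_legend_groups_are_toggle_complete():
    fig = _figure()
    assert fig.groups == ("AD", "control")
    svg = render_svg(fig)
    # one legend entry per group, and group classes on every expression trace
    assert svg.count('class="legend"') == 2
    assert 'data-group="0"' in svg and 'data-group="1"' in svg
    assert "grp-0" in svg and "grp-1" in svg


def test_export_html_self_contained_with_hover_payloads(tmp_path):
    fig = _figure()
    out = tmp_path / "fig.html"
    export_html(fig, out, self_contained=True)
    text = out.read_text()
    assert text.startswith("<!DOCTYPE html>")
    assert "<script>" in text and "src=" not in text  # runtime inline, no URLs
    assert "http" not in text.split("xmlns")[0]
    for fragment in ("Start: 100", "End: 200", "Length: 101", "Exon number: 1",
                     "Chromosome: chr1", "Transcript: T1"):
        assert fragment in text


def test_export_html_deterministic_bytes(tmp_path):
    a, b = tmp_path / "a.html", tmp_path / "b.html"
    export_html(_figure(seed=3), a)
    export_html(_figure(seed=3), b)
    assert a.read_bytes() == b.read_bytes()
    c = tmp_path / "c.html"
    export_html(_figure(seed=4), c)
    assert a.read_bytes() != c.read_bytes()  # jitter seed matters


def test_svg_static_export_one_rect_per_exon_and_cds(tmp_path):
    table = _structure_table()  # 2 exons + 1 CDS
    fig = assemble_figure(make_structure_panel(table, ["T1"]))
    out = tmp_path / "fig.svg"
    export_static(fig, out)
    svg = out.read_text()
    assert svg.count("<rect") == 3
    # determinism: same spec, same bytes
    out2 = tmp_path / "fig2.svg"
    export_static(fig, out2)
    assert out.read_bytes() == out2.read_bytes()


def test_static_export_png_pdf_and_unknown_format(tmp_path):
    fig = _figure()
    for fmt in ("png", "pdf"):
        path = tmp_path / f"f.{fmt}"
        export_static(fig, path, format=fmt)
        assert path.stat().st_size > 0
    with pytest.raises(ConfigurationError, match="tiff"):
        export_static(fig, tmp_path / "f.tiff", format="tiff")
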