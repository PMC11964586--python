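"""Figure assembly and export.

The figure is described first as a renderer-independent :class:`FigureSpec`
— shared transcript rows, a structure panel of shapes in display
coordinates, and one boxplot panel per expression metric — and only then
rendered. Interactive output is a self-contained HTML file: an inline SVG
plus a small embedded script providing hover tooltips, group legend
toggling and wheel zoom/pan, so the file works in a browser with no
network access. Static output is SVG (written directly, byte-deterministic)
or PNG/PDF (via matplotlib).

Boxplots follow the Tukey convention: median center line, quartile box
limits (linear-interpolation quartiles), whiskers to the most extreme data
points within 1.5 × IQR of the quartiles, points beyond drawn as outliers.
All raw points are overlaid with seeded jitter so figures are reproducible.
"""

from __future__ import annotations

import html as _html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import FeatureTable
from .errors import AssemblyError, ConfigurationError
from .expression import ExpressionTable

logger = logging.getLogger(__name__)

#: Exon boxes are drawn at half the height of CDS boxes.
EXON_HEIGHT_FRAC = 0.4
CDS_HEIGHT_FRAC = 0.8

#: Qualitative palette indexed by group order in the metadata.
PALETTE = [
    "#4C78A8", "#F58518", "#54A24B", "#E45756",
    "#72B7B2", "#EECA3B", "#B279A2", "#FF9DA6",
]

METRIC_LABELS = {
    "raw_count": "Counts",
    "cpm": "CPM",
    "relative_abundance": "Relative abundance (%)",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shape:
    """One drawable element of the structure panel, in display coords."""

    kind: str              # "exon" | "cds" | "intron" | "arrow"
    row: int
    x0: float
    x1: float
    height: float          # fraction of the row height
    strand: str
    hover: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BoxStats:
    """Five-number summary + outliers for one (transcript, group) cell."""

    transcript_id: str
    group: str
    median: float
    lower_quartile: float
    upper_quartile: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    points: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.upper_quartile - self.lower_quartile

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class StructurePanel:
    shapes: tuple[Shape, ...]
    row_order: tuple[str, ...]
    row_labels: tuple[str, ...]
    seqname: str


@dataclass(frozen=True)
class ExpressionPanel:
    metric: str
    title: str
    row_order: tuple[str, ...]
    boxes: tuple[BoxStats, ...]          # may hold several groups per row
    groups: tuple[str, ...]              # group order = legend order
    jitter: tuple[tuple[float, ...], ...]  # per box, one offset per point


@dataclass(frozen=True)
class FigureSpec:
    """Renderer-independent description of the linked figure."""

    row_order: tuple[str, ...]
    structure: StructurePanel
    expression_panels: tuple[ExpressionPanel, ...]
    groups: tuple[str, ...]
    colors: dict
    title: str
    jitter_seed: int


# ---------------------------------------------------------------------------
# structure panel
# ---------------------------------------------------------------------------

def _exon_hover(row, seqname: str) -> dict:
    gs = int(getattr(row, "genomic_start", row.start))
    ge = int(getattr(row, "genomic_end", row.end))
    num = row.exon_number
    return {
        "start": gs,
        "end": ge,
        "length": ge - gs + 1,
        "exon_number": int(num) if num is not None and not _isna(num) else "",
        "chromosome": seqname,
        "transcript": row.transcript_id,
    }


def _isna(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return x is None


def make_structure_panel(
    annotation: FeatureTable,
    row_order: list[str] | tuple[str, ...],
    arrow_spacing: float = 150.0,
) -> StructurePanel:
    """Build the transcript-structure panel fragment.

    Expects display coordinates (after gap rescaling) with the genomic
    coordinates preserved in ``genomic_start``/``genomic_end``; hover
    payloads always report genomic values. Introns are horizontal lines
    with strand-direction arrow markers at regular display intervals;
    exons are boxes; CDS are double-height boxes overdrawn on their exons.
    """
    df = annotation.df
    missing = [t for t in row_order if t not in set(df["transcript_id"])]
    if missing:
        raise AssemblyError(f"transcripts absent from annotation: {missing}")
    if "genomic_start" not in df.columns:
        df = df.assign(genomic_start=df["start"], genomic_end=df["end"])
    shapes: list[Shape] = []
    labels: list[str] = []
    for row_idx, tx in enumerate(row_order):
        sub = df[df["transcript_id"] == tx]
        strand = sub["strand"].iloc[0]
        seqname = sub["seqname"].iloc[0]
        name = sub["transcript_name"].iloc[0] or tx
        labels.append(name)
        for r in sub[sub["feature_kind"] == "intron"].itertuples(index=False):
            hover = {
                "start": int(r.genomic_start),
                "end": int(r.genomic_end),
                "length": int(r.genomic_end) - int(r.genomic_start) + 1,
                "chromosome": seqname,
                "transcript": tx,
            }
            shapes.append(Shape("intron", row_idx, float(r.start), float(r.end),
                                0.0, strand, hover))
            # arrow markers at fixed display intervals inside the intron
            x = float(r.start) + arrow_spacing / 2.0
            while x < float(r.end):
                shapes.append(Shape("arrow", row_idx, x, x, 0.0, strand, {}))
                x += arrow_spacing
        for r in sub[sub["feature_kind"] == "exon"].itertuples(index=False):
            shapes.append(Shape("exon", row_idx, float(r.start), float(r.end),
                                EXON_HEIGHT_FRAC, strand, _exon_hover(r, seqname)))
        for r in sub[sub["feature_kind"] == "CDS"].itertuples(index=False):
            shapes.append(Shape("cds", row_idx, float(r.start), float(r.end),
                                CDS_HEIGHT_FRAC, strand, _exon_hover(r, seqname)))
    seqname = df["seqname"].iloc[0]
    return StructurePanel(tuple(shapes), tuple(row_order), tuple(labels), seqname)


# ---------------------------------------------------------------------------
# box statistics
# ---------------------------------------------------------------------------

def _quantile_linear(sorted_values: np.ndarray, q: float) -> float:
    """Type-7 quantile: linear interpolation between order statistics.

    ``h = (n - 1) q``; the result is ``x[floor(h)] + (h - floor(h)) *
    (x[floor(h) + 1] - x[floor(h)])``. Written out explicitly so the rule
    is documented and the arithmetic is reproducible.
    """
    n = len(sorted_values)
    h = (n - 1) * q
    f = int(np.floor(h))
    c = min(f + 1, n - 1)
    lo, hi = float(sorted_values[f]), float(sorted_values[c])
    return lo + (h - f) * (hi - lo)


def _box_from_values(transcript_id: str, group: str, values: np.ndarray) -> BoxStats:
    v = np.sort(values)
    q1, med, q3 = (_quantile_linear(v, q) for q in (0.25, 0.50, 0.75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    return BoxStats(
        transcript_id=transcript_id,
        group=group,
        median=float(med),
        lower_quartile=float(q1),
        upper_quartile=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=tuple(float(v) for v in np.sort(outliers)),
        points=tuple(float(v) for v in values),
    )


def compute_box_stats(
    expr: ExpressionTable,
    metric: str,
    transcripts: list[str] | tuple[str, ...],
    group_var: str,
) -> list[BoxStats]:
    """Per (transcript, group) Tukey box statistics for one metric.

    Quartiles use linear interpolation between order statistics; fences sit
    at Q1 − 1.5·IQR and Q3 + 1.5·IQR; whiskers end at the most extreme data
    values inside the fences. Group order follows first appearance in the
    table. Empty (transcript, group) cells yield an empty BoxStats with a
    warning.
    """
    if group_var not in expr.df.columns:
        raise ConfigurationError(
            f"group variable {group_var!r} not in expression table "
            f"(have {sorted(expr.df.columns)})"
        )
    if metric not in expr.df.columns:
        raise ConfigurationError(f"metric {metric!r} not computed on this table")
    groups = list(dict.fromkeys(expr.df[group_var].tolist()))
    out: list[BoxStats] = []
    for tx in transcripts:
        for grp in groups:
            values = expr.df.loc[
                (expr.df["transcript_id"] == tx) & (expr.df[group_var] == grp),
                metric,
            ].to_numpy(dtype=float)
            if values.size == 0:
                logger.warning("no %s values for transcript %s group %s", metric, tx, grp)
                out.append(BoxStats(tx, str(grp), np.nan, np.nan, np.nan,
                                    np.nan, np.nan, (), ()))
                continue
            out.append(_box_from_values(tx, str(grp), values))
    return out


def make_expression_panel(
    expr: ExpressionTable,
    metric: str,
    row_order: list[str] | tuple[str, ...],
    group_var: str,
    seed: int = 0,
    title: str | None = None,
) -> ExpressionPanel:
    """Boxplot panel fragment: BoxStats plus seeded-jitter point overlays."""
    boxes = compute_box_stats(expr, metric, list(row_order), group_var)
    groups = tuple(dict.fromkeys(b.group for b in boxes))
    rng = np.random.default_rng(seed)
    jitter = tuple(
        tuple(float(v) for v in rng.uniform(-0.5, 0.5, size=len(b.points)))
        for b in boxes
    )
    return ExpressionPanel(
        metric=metric,
        title=title or METRIC_LABELS.get(metric, metric),
        row_order=tuple(row_order),
        boxes=tuple(boxes),
        groups=groups,
        jitter=jitter,
    )


# ---------------------------------------------------------------------------
# figure assembly
# ---------------------------------------------------------------------------

def assemble_figure(
    structure: StructurePanel,
    expression_panels: list[ExpressionPanel] | tuple[ExpressionPanel, ...] = (),
    row_order: list[str] | tuple[str, ...] | None = None,
    title: str = "",
    jitter_seed: int = 0,
    palette: list[str] | None = None,
) -> FigureSpec:
    """Combine the panel fragments into one FigureSpec.

    All fragments must share the same row order: every transcript occupies
    the same vertical position in every panel. Each metadata group gets one
    legend entry that toggles that group's traces across all expression
    panels simultaneously.
    """
    row_order = tuple(row_order) if row_order is not None else structure.row_order
    if tuple(structure.row_order) != row_order:
        raise AssemblyError(
            f"structure panel rows {structure.row_order} != figure rows {row_order}"
        )
    for panel in expression_panels:
        if tuple(panel.row_order) != row_order:
            raise AssemblyError(
                f"panel {panel.metric!r} rows {panel.row_order} != figure rows {row_order}"
            )
    groups: tuple[str, ...] = ()
    for panel in expression_panels:
        if groups and panel.groups != groups:
            raise AssemblyError("expression panels disagree on group order")
        groups = panel.groups
    pal = palette or PALETTE
    colors = {g: pal[i % len(pal)] for i, g in enumerate(groups)}
    return FigureSpec(
        row_order=row_order,
        structure=structure,
        expression_panels=tuple(expression_panels),
        groups=groups,
        colors=colors,
        title=title,
        jitter_seed=jitter_seed,
    )


# ---------------------------------------------------------------------------
# SVG rendering (deterministic)
# ---------------------------------------------------------------------------

_ROW_H = 46
_MARGIN = dict(left=150, right=30, top=70, bottom=45)
_STRUCT_W = 620
_EXPR_W = 240
_PANEL_GAP = 40


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _hover_text(hover: dict) -> str:
    order = ["start", "end", "length", "exon_number", "chromosome", "transcript"]
    lines = []
    for key in order:
        if key in hover and hover[key] != "":
            label = key.replace("_", " ").capitalize()
            lines.append(f"{label}: {hover[key]}")
    return "\n".join(lines)


class _SvgWriter:
    def __init__(self) -> None:
        self.parts: list[str] = []

    def add(self, s: str) -> None:
        self.parts.append(s)

    def rect(self, x, y, w, h, fill, cls="", hover="", extra="") -> None:
        attrs = f'x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" fill="{fill}"'
        if cls:
            attrs += f' class="{cls}"'
        if hover:
            attrs += f' data-hover="{_html.escape(hover)}"'
        if extra:
            attrs += " " + extra
        self.add(f"<rect {attrs}/>")

    def line(self, x1, y1, x2, y2, stroke, width=1.5, cls="", hover="") -> None:
        attrs = (f'x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                 f'stroke="{stroke}" stroke-width="{_fmt(width)}"')
        if cls:
            attrs += f' class="{cls}"'
        if hover:
            attrs += f' data-hover="{_html.escape(hover)}"'
        self.add(f"<line {attrs}/>")

    def path(self, d, stroke="none", fill="none", cls="") -> None:
        attrs = f'd="{d}" stroke="{stroke}" fill="{fill}"'
        if cls:
            attrs += f' class="{cls}"'
        self.add(f"<path {attrs}/>")

    def text(self, x, y, s, size=12, anchor="start", cls="", rotate=None) -> None:
        attrs = (f'x="{_fmt(x)}" y="{_fmt(y)}" font-size="{size}" '
                 f'text-anchor="{anchor}" font-family="sans-serif"')
        if cls:
            attrs += f' class="{cls}"'
        if rotate is not None:
            attrs += f' transform="rotate({rotate} {_fmt(x)} {_fmt(y)})"'
        self.add(f"<text {attrs}>{_html.escape(str(s))}</text>")

    def circle(self, cx, cy, r, fill, cls="", hover="") -> None:
        attrs = f'cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="{fill}"'
        if cls:
            attrs += f' class="{cls}"'
        if hover:
            attrs += f' data-hover="{_html.escape(hover)}"'
        self.add(f"<circle {attrs}/>")


def _figure_geometry(fig: FigureSpec) -> dict:
    n_rows = len(fig.row_order)
    width = (_MARGIN["left"] + _STRUCT_W
             + len(fig.expression_panels) * (_PANEL_GAP + _EXPR_W)
             + _MARGIN["right"])
    height = _MARGIN["top"] + max(n_rows, 1) * _ROW_H + _MARGIN["bottom"]
    return dict(width=width, height=height, n_rows=n_rows)


def _render_structure(w: _SvgWriter, fig: FigureSpec, x0: float) -> None:
    panel = fig.structure
    shapes = panel.shapes
    if shapes:
        dmin = min(s.x0 for s in shapes)
        dmax = max(s.x1 for s in shapes)
    else:
        dmin, dmax = 0.0, 1.0
    span = max(dmax - dmin, 1e-9)
    scale = _STRUCT_W / span

    def X(d: float) -> float:
        return x0 + (d - dmin) * scale

    def Y(row: int) -> float:
        return _MARGIN["top"] + (row + 0.5) * _ROW_H

    for row, label in enumerate(panel.row_labels):
        w.text(x0 - 10, Y(row) + 4, label, anchor="end")
    for s in shapes:
        y = Y(s.row)
        if s.kind == "intron":
            w.line(X(s.x0), y, X(s.x1), y, "#555555", 1.5,
                   cls="intron", hover=_hover_text(s.hover))
        elif s.kind == "arrow":
            # chevron pointing in the strand's transcription direction
            dx = 4.0 if s.strand == "+" else -4.0
            px = X(s.x0)
            w.path(f"M {_fmt(px - dx)} {_fmt(y - 4)} L {_fmt(px + dx)} {_fmt(y)} "
                   f"L {_fmt(px - dx)} {_fmt(y + 4)}",
                   stroke="#555555", cls=f"arrow strand-{'plus' if s.strand == '+' else 'minus'}")
    # exon boxes first, CDS overdrawn taller
    for kind, fill in (("exon", "#9ecae1"), ("cds", "#3182bd")):
        for s in shapes:
            if s.kind != kind:
                continue
            y = Y(s.row)
            h = s.height * _ROW_H
            w.rect(X(s.x0), y - h / 2, max((s.x1 - s.x0) * scale, 1.0), h,
                   fill, cls=kind, hover=_hover_text(s.hover))
    w.text(x0 + _STRUCT_W / 2, _MARGIN["top"] - 14,
           f"Transcript structure ({panel.seqname})", size=13, anchor="middle")


def _render_expression(w: _SvgWriter, fig: FigureSpec, panel: ExpressionPanel,
                       x0: float) -> None:
    finite = [v for b in panel.boxes for v in (*b.points, b.whisker_low, b.whisker_high)
              if v == v]
    vmin = min(finite, default=0.0)
    vmax = max(finite, default=1.0)
    if vmin == vmax:
        vmin, vmax = vmin - 1.0, vmax + 1.0
    pad = 0.05 * (vmax - vmin)
    vmin, vmax = vmin - pad, vmax + pad
    scale = _EXPR_W / (vmax - vmin)

    def X(v: float) -> float:
        return x0 + (v - vmin) * scale

    n_groups = max(len(panel.groups), 1)
    slot = _ROW_H * 0.8 / n_groups
    box_h = slot * 0.6

    def Y(row: int, gi: int) -> float:
        top = _MARGIN["top"] + row * _ROW_H + 0.1 * _ROW_H
        return top + (gi + 0.5) * slot

    w.text(x0 + _EXPR_W / 2, _MARGIN["top"] - 14, panel.title, size=13, anchor="middle")
    # panel frame
    h_total = len(fig.row_order) * _ROW_H
    w.path(f"M {_fmt(x0)} {_fmt(_MARGIN['top'])} V {_fmt(_MARGIN['top'] + h_total)} "
           f"H {_fmt(x0 + _EXPR_W)}", stroke="#999999")
    row_of = {t: i for i, t in enumerate(panel.row_order)}
    gi_of = {g: i for i, g in enumerate(panel.groups)}
    for b, jit in zip(panel.boxes, panel.jitter):
        if b.n == 0:
            continue
        row, gi = row_of[b.transcript_id], gi_of[b.group]
        y = Y(row, gi)
        color = fig.colors.get(b.group, "#888888")
        cls = f"grp grp-{gi}"
        hover = (f"Transcript: {b.transcript_id}\nGroup: {b.group}\n"
                 f"Median: {_fmt(b.median)}\nQ1: {_fmt(b.lower_quartile)}\n"
                 f"Q3: {_fmt(b.upper_quartile)}\n"
                 f"Whiskers: [{_fmt(b.whisker_low)}, {_fmt(b.whisker_high)}]\n"
                 f"n: {b.n}")
        # whisker line, box, median
        w.line(X(b.whisker_low), y, X(b.whisker_high), y, color, 1.0, cls=cls)
        w.rect(X(b.lower_quartile), y - box_h / 2,
               max((b.upper_quartile - b.lower_quartile) * scale, 0.5), box_h,
               color, cls=f"box {cls}", hover=hover, extra='fill-opacity="0.45"')
        w.line(X(b.median), y - box_h / 2, X(b.median), y + box_h / 2, color, 2.0, cls=cls)
        for v, off in zip(b.points, jit):
            w.circle(X(v), y + off * box_h, 2.2, color, cls=f"pt {cls}",
                     hover=f"Transcript: {b.transcript_id}\nGroup: {b.group}\n"
                           f"Value: {_fmt(v)}")
        for v in b.outliers:
            w.circle(X(v), y, 3.0, "none", cls=cls)  # ring marks the outlier
            w.circle(X(v), y, 1.2, color, cls=cls)
    # axis ticks: min / max
    w.text(x0, _MARGIN["top"] + h_total + 16, _fmt(vmin + pad), size=10, anchor="start")
    w.text(x0 + _EXPR_W, _MARGIN["top"] + h_total + 16, _fmt(vmax - pad), size=10,
           anchor="end")


def render_svg(fig: FigureSpec, interactive: bool = False) -> str:
    """Render the FigureSpec to an SVG string (deterministic)."""
    geo = _figure_geometry(fig)
    w = _SvgWriter()
    w.add(f'<svg xmlns="http://www.w3.org/2000/svg" id="isoviz-figure" '
          f'width="{geo["width"]}" height="{geo["height"]}" '
          f'viewBox="0 0 {geo["width"]} {geo["height"]}">')
    if fig.title:
        w.text(geo["width"] / 2, 22, fig.title, size=15, anchor="middle")
    _render_structure(w, fig, _MARGIN["left"])
    x = _MARGIN["left"] + _STRUCT_W
    for panel in fig.expression_panels:
        x += _PANEL_GAP
        _render_expression(w, fig, panel, x)
        x += _EXPR_W
    # legend: one toggleable entry per metadata group
    if fig.groups:
        lx = _MARGIN["left"]
        ly = 40
        for gi, g in enumerate(fig.groups):
            w.add(f'<g class="legend" data-group="{gi}" style="cursor:pointer">')
            w.circle(lx + 6, ly - 4, 6, fig.colors[g])
            w.text(lx + 18, ly, g, size=12)
            w.add("</g>")
            lx += 18 + 8 * len(str(g)) + 30
    w.add("</svg>")
    return "\n".join(w.parts) + "\n"


_HTML_SCRIPT = """
(function () {
  var svg = document.getElementById('isoviz-figure');
  var tip = document.getElementById('isoviz-tooltip');
  svg.addEventListener('mousemove', function (ev) {
    var t = ev.target.closest('[data-hover]');
    if (t) {
      tip.textContent = t.getAttribute('data-hover');
      tip.style.display = 'block';
      tip.style.left = (ev.pageX + 12) + 'px';
      tip.style.top = (ev.pageY + 12) + 'px';
    } else {
      tip.style.display = 'none';
    }
  });
  svg.addEventListener('mouseleave', function () { tip.style.display = 'none'; });
  // legend toggling: one entry per group controls that group's traces
  svg.querySelectorAll('.legend').forEach(function (entry) {
    entry.addEventListener('click', function () {
      var gi = entry.getAttribute('data-group');
      var hidden = entry.classList.toggle('legend-off');
      entry.style.opacity = hidden ? 0.35 : 1.0;
      svg.querySelectorAll('.grp-' + gi).forEach(function (el) {
        el.style.display = hidden ? 'none' : '';
      });
    });
  });
  // wheel zoom + drag pan via the viewBox
  var vb = svg.viewBox.baseVal;
  var home = [vb.x, vb.y, vb.width, vb.height];
  svg.addEventListener('wheel', function (ev) {
    ev.preventDefault();
    var k = ev.deltaY < 0 ? 0.9 : 1.1;
    var pt = svg.createSVGPoint();
    pt.x = ev.clientX; pt.y = ev.clientY;
    var p = pt.matrixTransform(svg.getScreenCTM().inverse());
    vb.x = p.x - (p.x - vb.x) * k;
    vb.y = p.y - (p.y - vb.y) * k;
    vb.width *= k; vb.height *= k;
  }, {passive: false});
  var drag = null;
  svg.addEventListener('mousedown', function (ev) { drag = [ev.clientX, ev.clientY]; });
  window.addEventListener('mouseup', function () { drag = null; });
  svg.addEventListener('mousemove', function (ev) {
    if (!drag) return;
    var sc = vb.width / svg.clientWidth;
    vb.x -= (ev.clientX - drag[0]) * sc;
    vb.y -= (ev.clientY - drag[1]) * sc;
    drag = [ev.clientX, ev.clientY];
  });
  svg.addEventListener('dblclick', function () {
    vb.x = home[0]; vb.y = home[1]; vb.width = home[2]; vb.height = home[3];
  });
})();
"""


def export_html(fig: FigureSpec, path: str | Path, self_contained: bool = True) -> None:
    """Write the interactive figure as a single HTML file.

    The rendering runtime (tooltip, legend toggling, zoom/pan) is a small
    script embedded in the file, so the output is always self-contained
    and viewable offline; the flag is kept for API symmetry with renderers
    that can defer to an external runtime.
    """
    svg = render_svg(fig, interactive=True)
    doc = (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset=\"utf-8\"/>\n"
        f"<title>{_html.escape(fig.title or 'isoviz figure')}</title>\n"
        "<style>\n"
        "#isoviz-tooltip {position:absolute; display:none; background:#222;"
        " color:#fff; padding:6px 8px; border-radius:4px; font:12px sans-serif;"
        " white-space:pre; pointer-events:none; z-index:10;}\n"
        "</style>\n</head>\n<body>\n"
        f"{svg}"
        "<div id=\"isoviz-tooltip\"></div>\n"
        f"<script>{_HTML_SCRIPT}</script>\n"
        "</body>\n</html>\n"
    )
    Path(path).write_text(doc, encoding="utf-8")


def export_static(fig: FigureSpec, path: str | Path, format: str | None = None) -> None:
    """Write a static image: SVG (native, deterministic), PNG or PDF.

    PNG/PDF rendering goes through matplotlib; an unavailable backend
    raises a clear error suggesting HTML export instead.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        path.write_text(render_svg(fig, interactive=False), encoding="utf-8")
        return
    if fmt not in ("png", "pdf"):
        raise ConfigurationError(
            f"unknown static format {fmt!r}; supported: svg, png, pdf"
        )
    try:
        _export_matplotlib(fig, path, fmt)
    except ImportError as exc:
        raise ConfigurationError(
            f"static {fmt} backend unavailable ({exc}); use export_html instead"
        ) from exc


def _export_matplotlib(fig: FigureSpec, path: Path, fmt: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    geo = _figure_geometry(fig)
    mfig, ax = plt.subplots(figsize=(geo["width"] / 90, geo["height"] / 90))
    ax.set_xlim(0, geo["width"])
    ax.set_ylim(geo["height"], 0)
    ax.axis("off")
    # reuse the SVG layout by replaying the structure panel geometry
    panel = fig.structure
    shapes = panel.shapes
    dmin = min((s.x0 for s in shapes), default=0.0)
    dmax = max((s.x1 for s in shapes), default=1.0)
    scale = _STRUCT_W / max(dmax - dmin, 1e-9)
    x0 = _MARGIN["left"]
    for row, label in enumerate(panel.row_labels):
        y = _MARGIN["top"] + (row + 0.5) * _ROW_H
        ax.text(x0 - 10, y, label, ha="right", va="center", fontsize=8)
    for s in shapes:
        y = _MARGIN["top"] + (s.row + 0.5) * _ROW_H
        if s.kind == "intron":
            ax.plot([x0 + (s.x0 - dmin) * scale, x0 + (s.x1 - dmin) * scale],
                    [y, y], color="#555555", lw=1)
        elif s.kind in ("exon", "cds"):
            h = s.height * _ROW_H
            color = "#9ecae1" if s.kind == "exon" else "#3182bd"
            ax.add_patch(Rectangle((x0 + (s.x0 - dmin) * scale, y - h / 2),
                                   max((s.x1 - s.x0) * scale, 1.0), h, color=color))
    x = _MARGIN["left"] + _STRUCT_W
    for p in fig.expression_panels:
        x += _PANEL_GAP
        finite = [v for b in p.boxes for v in b.points]
        vmin, vmax = (min(finite), max(finite)) if finite else (0.0, 1.0)
        if vmin == vmax:
            vmin, vmax = vmin - 1, vmax + 1
        vscale = _EXPR_W / (vmax - vmin)
        gi_of = {g: i for i, g in enumerate(p.groups)}
        slot = _ROW_H * 0.8 / max(len(p.groups), 1)
        for b in p.boxes:
            if b.n == 0:
                continue
            row = list(p.row_order).index(b.transcript_id)
            y = (_MARGIN["top"] + row * _ROW_H + 0.1 * _ROW_H
                 + (gi_of[b.group] + 0.5) * slot)
            color = fig.colors.get(b.group, "#888888")
            ax.plot([x + (b.whisker_low - vmin) * vscale,
                     x + (b.whisker_high - vmin) * vscale], [y, y], color=color, lw=1)
            ax.add_patch(Rectangle((x + (b.lower_quartile - vmin) * vscale,
                                    y - slot * 0.3),
                                   max((b.iqr) * vscale, 0.5), slot * 0.6,
                                   color=color, alpha=0.45))
        x += _EXPR_W
    if fig.title:
        ax.set_title(fig.title)
    mfig.savefig(path, format=fmt, dpi=120)
    plt.close(mfig)
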