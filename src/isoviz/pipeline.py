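"""End-to-end pipeline: files in, linked figure out.

Stage order is fixed and logged: read → validate → normalize → filter gene
→ rank/select → number/intronize → gap-map → render → export.
Normalization deliberately precedes gene filtering: the CPM library size
is the column total of the full supplied matrix, so subsetting first would
silently change the numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import annotation as ann_io
from . import expression as expr_io
from . import rendering, transform
from .errors import ConfigurationError, IsovizError, ValidationError

logger = logging.getLogger(__name__)

FORMATS = ("html", "svg", "png", "pdf")


@dataclass(frozen=True)
class RunConfig:
    """Everything one plotting run needs; serializable to/from YAML."""

    gtf: str = ""
    counts: str = ""
    metadata: str = ""
    gene: str = ""
    top_n: int = 5
    metric: str = "cpm"               # ranking metric
    reducer: str = "mean"
    rescale_cap: float = 100.0
    panels: tuple[str, ...] = ("cpm",)  # expression panels to draw
    group_var: str = "condition"
    output: str = "figure.html"
    format: str = "html"
    seed: int = 0
    case_insensitive: bool = False
    arrow_spacing: float = 150.0
    id_column: str = "transcript_id"
    overwrite: bool = True
    verbosity: int = 0

    def validated(self) -> "RunConfig":
        if self.format not in FORMATS:
            raise ConfigurationError(
                f"unknown output format {self.format!r}; use one of {FORMATS}"
            )
        if self.top_n < 1:
            raise ConfigurationError("top_n must be positive")
        return self


def _stage(name: str, message: str, *args) -> None:
    logger.info("[%s] " + message, name, *args)


def load_inputs(config: RunConfig):
    """Read and cross-validate the three input files."""
    for label, path in (("gtf", config.gtf), ("counts", config.counts),
                        ("metadata", config.metadata)):
        if path and not Path(path).exists():
            raise IsovizError(f"[read] {label} file not found: {path}")
    annotation = ann_io.read_gtf(config.gtf)
    _stage("read", "annotation: %d records, %d transcripts",
           len(annotation), len(annotation.transcript_ids))
    expr = expr_io.read_expression(config.counts, id_column=config.id_column)
    _stage("read", "expression: %d rows, %d samples", len(expr), len(expr.sample_ids))
    meta = expr_io.read_metadata(config.metadata)
    _stage("read", "metadata: %d samples, variables %s",
           len(meta.df), meta.group_variables)
    report = ann_io.check_expression_consistency(annotation, expr)
    _stage("validate", "transcript IDs: %d shared, %d annotation-only, %d expression-only",
           len(report.shared), len(report.annotation_only), len(report.expression_only))
    return annotation, expr, meta, report


def normalize(annotation, expr, meta, report):
    """Join metadata and compute both normalizations on the full matrix."""
    expr = expr_io.join_metadata(expr, meta)
    expr = expr_io.normalize_cpm(expr)
    if report.expression_only:
        logger.warning(
            "[normalize] dropping %d transcripts absent from the annotation "
            "before relative abundance", len(report.expression_only)
        )
        expr = expr.subset_transcripts(report.shared)
    gene_of = dict(
        annotation.df.loc[annotation.df["transcript_id"] != "",
                          ["transcript_id", "gene_id"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    expr = expr_io.normalize_relative_abundance(expr, gene_of)
    _stage("normalize", "cpm + relative abundance on %d rows", len(expr))
    return expr


def build_figure(annotation, expr, config: RunConfig) -> rendering.FigureSpec:
    """Gene-level stages: filter, rank, enhance annotation, map, assemble."""
    config = config.validated()
    gene_ann, gene_expr = transform.filter_gene(
        annotation, expr, config.gene, case_insensitive=config.case_insensitive
    )
    _stage("filter", "gene %s: %d records, %d transcripts",
           config.gene, len(gene_ann), len(gene_ann.transcript_ids))
    if gene_expr is not None and len(gene_expr):
        row_order = transform.rank_and_select(
            gene_expr, metric=config.metric, reducer=config.reducer,
            top_n=config.top_n,
        )
    else:
        # structure-only runs (no expression) show every isoform of the gene
        row_order = sorted(gene_ann.transcript_ids)
    _stage("select", "top %d transcripts: %s", len(row_order), row_order)
    gene_ann = transform.add_exon_number(gene_ann)
    gene_ann = transform.to_intron(gene_ann)
    keep = set(row_order)
    gene_ann = ann_io.FeatureTable(
        gene_ann.df[gene_ann.df["transcript_id"].isin(keep)].reset_index(drop=True),
        dict(gene_ann.provenance),
    )
    gap_map = transform.build_gap_map(gene_ann, cap=config.rescale_cap,
                                      transcripts=row_order)
    display_ann = transform.apply_gap_map(gap_map, gene_ann)
    _stage("gap-map", "%d segments, cap %g", len(gap_map.segments), gap_map.cap)
    structure = rendering.make_structure_panel(
        display_ann, row_order, arrow_spacing=config.arrow_spacing
    )
    panels = []
    if gene_expr is not None and len(gene_expr):
        gene_expr = gene_expr.subset_transcripts(keep)
        for metric in config.panels:
            panels.append(
                rendering.make_expression_panel(
                    gene_expr, metric, row_order, config.group_var,
                    seed=config.seed,
                )
            )
    fig = rendering.assemble_figure(
        structure, panels, row_order,
        title=config.gene, jitter_seed=config.seed,
    )
    _stage("render", "figure: %d rows, %d expression panels",
           len(fig.row_order), len(fig.expression_panels))
    return fig


def export(fig: rendering.FigureSpec, config: RunConfig) -> Path:
    out = Path(config.output)
    if out.exists() and not config.overwrite:
        raise IsovizError(f"[export] output exists and overwrite is disabled: {out}")
    if config.format == "html":
        rendering.export_html(fig, out, self_contained=True)
    else:
        rendering.export_static(fig, out, format=config.format)
    _stage("export", "%s written (%d bytes)", out, out.stat().st_size)
    return out


def run_plot(config: RunConfig) -> Path:
    """The single-gene pipeline; returns the output path."""
    config = config.validated()
    annotation, expr, meta, report = load_inputs(config)
    expr = normalize(annotation, expr, meta, report)
    fig = build_figure(annotation, expr, config)
    return export(fig, config)


def run_batch(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """One structure plot per gene in the annotation.

    Genes that fail validation (e.g. overlapping exons) are logged and
    skipped, never fatal. Returns the manifest (gene, file, status) and
    writes it as ``manifest.csv`` in *out_dir*.
    """
    config = config.validated()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = ann_io.read_gtf(config.gtf)
    genes = list(dict.fromkeys(annotation.df["gene_id"]))
    if not genes:
        raise ValidationError("annotation contains zero genes")
    expr = meta = None
    if config.counts and config.metadata:
        _, expr0, meta0, report = load_inputs(config)
        expr = normalize(annotation, expr0, meta0, report)
    rows = []
    for gene in genes:
        target = out_dir / f"{gene}.{config.format}"
        if target.exists() and not config.overwrite:
            raise IsovizError(
                f"[batch] output exists and overwrite is disabled: {target}"
            )
        gene_cfg = replace(config, gene=gene, output=str(target))
        try:
            if expr is not None:
                fig = build_figure(annotation, expr, gene_cfg)
            else:
                fig = build_figure(annotation, None, gene_cfg)
            export(fig, gene_cfg)
            rows.append({"gene": gene, "file": str(target), "status": "ok"})
        except IsovizError as exc:
            logger.warning("[batch] skipping gene %s: %s", gene, exc)
            rows.append({"gene": gene, "file": "", "status": f"skipped: {exc}"})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    _stage("batch", "%d genes, %d written, %d skipped", len(genes),
           int((manifest["status"] == "ok").sum()),
           int((manifest["status"] != "ok").sum()))
    return manifest
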