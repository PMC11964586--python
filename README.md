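# isoviz

Linked, interactive visualization of RNA isoform structure and per-isoform
expression.

Alternative splicing lets one gene produce many RNA isoforms with distinct
exon compositions and, often, distinct functions. Interpreting isoform-level
quantification — now routine with long-read sequencing — needs figures that
show, side by side, *what each isoform looks like* (its exons, coding
sequence and introns) and *how much of it each sample expresses*. isoviz is
a Python library plus a thin CLI for exactly that: it ingests an
ENSEMBL-dialect GTF and a transcript-level counts matrix, normalizes,
selects and orders the most expressed isoforms, computes display
coordinates, and renders one figure in which every isoform occupies the
same row of a transcript-structure panel and one or more expression
boxplot panels, exported as a single self-contained interactive HTML file
(hover details, group legend toggling, zoom/pan — no network needed) or as
static SVG/PNG/PDF.

## What it computes

**Normalization.** For counts `x_ts` of transcript *t* in sample *s*:

- counts per million: `CPM_ts = x_ts / Σ_t' x_t's × 10⁶` (library = column
  total of the supplied matrix);
- relative transcript abundance: `RA_ts = x_ts / Σ_{t'∈gene(t)} x_t's × 100`,
  a transcript's percent share of its gene in that sample.

**Isoform selection.** Transcripts are ranked by a reducer (mean, median or
sum across samples) of a chosen metric, descending, ties broken by
transcript ID; the top *n* are displayed in rank order.

**Display coordinates.** Exon numbering follows transcription order
(ascending starts on `+`, descending on `-`); introns are derived as the
gaps between consecutive exons. Long introns are rescaled with a shared
piecewise-linear map built from the union of exon intervals across all
displayed isoforms: covered regions keep genomic scale, every uncovered gap
is compressed to at most `cap` display units (default 100). Exon and CDS
lengths are preserved exactly and all isoforms of a gene stay aligned on
one axis.

**Expression panels.** Tukey boxplots per (isoform, group): median,
linear-interpolation quartiles, whiskers to the most extreme points within
1.5 × IQR of the box, points beyond drawn as outliers, all raw points
overlaid with seeded jitter. CDS segments are drawn as boxes twice the
height of non-coding exon regions.

## Worked example

`examples/01_linked_isoform_figure.py` generates a synthetic case/control
dataset (8 samples: 4 "AD", 4 "control"; the focal gene has 6 isoforms)
and plots the top five expressed isoforms:

```
gene SIMG00001: 6 isoforms, top 5 plotted
expected rank order: ['SIMT001006', 'SIMT001004', 'SIMT001005', 'SIMT001002', 'SIMT001003']
figure: .../figure.html (30215 bytes, self-contained HTML)
```

The five rows are the five most expressed isoforms, highest first. Opening
the HTML in a browser, hovering an exon shows its genomic start/end,
length, exon number, chromosome and transcript; clicking a legend entry
hides that group's boxplots and points in every expression panel at once.

The rescaling behaviour (`examples/03_intron_rescaling.py`): two 100 bp
exons separated by a 9 900 bp intron map to

```
exon    genomic (     1,    100) len   100 -> display (     1,    100) len   100
exon    genomic ( 10001,  10100) len   100 -> display (   201,    300) len   100
intron  genomic (   101,  10000) len  9900 -> display (   101,    200) len   100
```

— exon lengths unchanged, the intron drawn as exactly the 100-unit cap.

The same pipeline from the shell:

```bash
isoviz simulate --out-dir demo --seed 1
isoviz plot --gtf demo/annotation.gtf --counts demo/counts.csv \
    --metadata demo/metadata.csv --gene SIMG00001 --top-n 5 \
    --output figure.html
isoviz batch --gtf demo/annotation.gtf --out-dir plots/   # one plot per gene
```

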