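# Methods

## Data model and conventions

All coordinates are 1-based inclusive (the GTF convention); interval length
is `end − start + 1`. The same convention holds for display coordinates
after rescaling, so there is a single rule everywhere. Annotation lives in
a long-form `FeatureTable` (gene/transcript/exon/CDS/intron rows);
expression in a long-form `ExpressionTable` of (transcript, sample) rows
with group labels joined from the sample metadata.

The GTF reader accepts both the quoted ENSEMBL attribute dialect
(`key "value";`) and unquoted `key value;` pairs (lenient mode, on by
default); unknown attribute keys are ignored. Missing `gene_name` falls
back to `gene_id` and missing `transcript_name` to `transcript_id`, so
display labels are never empty. Records with `.` or `?` strand are
rejected rather than defaulted: exon numbering and intron direction arrows
are strand-dependent, and a silent default would mislabel them. Duplicate
identical records are dropped with a warning. Transcript extent rows are
optional; a transcript's span is always derivable as (min exon start, max
exon end). The writer emits attributes in a fixed key order and omits
empty optional fields, giving an exact write→read round-trip.

## Normalization

For raw counts `x_ts`:

- **CPM**: `x_ts / Σ_t' x_t's × 10⁶`. The library size is the column total
  of the matrix *as supplied*. This matters: subsetting to one gene before
  normalizing changes every CPM, so the pipeline normalizes before gene
  filtering, always.
- **Relative transcript abundance**: `x_ts / Σ_{t'∈gene(t)} x_t's × 100`,
  percent of the gene total per sample — the isoform-usage quantity.

Zero denominators (a zero library, a gene with zero counts in a sample)
yield 0 with a logged warning rather than NaN, keeping sparse fixtures
renderable. Missing matrix cells are read as 0 (warned), not dropped, so
matrices stay rectangular. Length-aware normalizations (TPM/FPKM) are out
of scope.

## Isoform selection

Transcripts are ordered by `reducer(metric)` across samples, descending,
with metric ∈ {raw_count, cpm, relative_abundance} and reducer ∈ {mean,
median, sum} (default mean). Ties break lexicographically on transcript ID
so the order is total and reproducible. `top_n` larger than the available
set returns everything with a warning.

## Annotation enhancement

**Exon numbering** is 1..n in transcription order: ascending genomic start
on `+`, descending on `-`. CDS records inherit the number of the exon that
contains them; a CDS contained in no exon is a validation error.

**Intron derivation**: with exons sorted by start, each consecutive pair
contributes the intron `(prev.end + 1, next.start − 1)`; adjacent or
overlapping-with-tolerance pairs contribute none, and truly overlapping
exons within one transcript are an error. Exon plus intron lengths tile
the transcript span exactly.

## The gap map

The display axis is built once per plotted locus from the **union of exon
intervals across all displayed transcripts** — never per transcript — so
every isoform shares one axis and vertically aligned features are truly
aligned. Covered (exon-union) segments keep genomic scale. Each uncovered
gap of length `L` is compressed to `min(L, cap)` display units, uniformly
within the gap; gaps already ≤ cap are untouched. The default cap is 100
bp-equivalents, chosen so a compressed intron remains a visible but modest
line segment next to typical exons (tens to hundreds of bp). A fixed cap,
rather than proportional shrinking, keeps the rule local (one gap's length
never influences another's display size) and makes the identity limit
(cap ≥ longest gap) exact.

Formally, with cumulative display length `c(p)` through genomic base `p`
(each covered base contributes 1, each base of gap `i` contributes
`min(L_i, cap)/L_i`), a feature `[s, e]` maps to display
`[c(s−1) + 1, c(e)]`. Boundary display coordinates are integers whenever
the cap is an integer; the map is strictly increasing, exon/CDS display
lengths equal genomic lengths exactly, and applying build+apply a second
time (all gaps now ≤ cap) is the identity. The segment-based implementation
is checked against a literal per-base walk on random loci up to 50 kb.

Hover payloads always report **genomic** coordinates and lengths; display
coordinates are a drawing device only.

## Box statistics and rendering

Quartiles use linear interpolation between order statistics
(`h = (n−1)q`; type-7, the numpy/R default), written out explicitly so the
arithmetic is reproducible. Fences sit at Q1 − 1.5·IQR and Q3 + 1.5·IQR;
whiskers end at the most extreme data values inside the fences (falling
back to the quartiles when no point lies beyond them); points outside are
outliers; all raw points are retained and overlaid with jitter drawn from
a seeded generator, so identical inputs and seed give byte-identical
figures.

The figure is assembled as a renderer-independent `FigureSpec`: shared row
order (one row per isoform, in rank order), a structure panel of shapes in
display coordinates, and one panel per expression metric. Exon boxes are
drawn at half the height of CDS boxes (0.4 vs 0.8 of the row height).
Strand-direction chevrons are placed on intron lines only, at a fixed
display interval (default 150 units, configurable). Colors come from one
qualitative palette indexed by group order in the metadata.

Rendering is the package's own deterministic SVG writer. Interactive HTML
embeds that SVG plus a small inline script (tooltip from per-shape
payloads, one clickable legend entry per metadata group toggling that
group's traces in every panel, wheel zoom and drag pan on the viewBox);
the file is always self-contained and works offline. Static export writes
the same SVG directly (byte-deterministic; exactly one `<rect>` per
exon/CDS record in a structure-only figure) or rasterizes through
matplotlib for PNG/PDF.

## Synthetic data generator

The generator emulates the study shape the pipeline targets: a handful of
genes on both strands, each a skeleton of exon blocks from which every
isoform samples a subset (so one isoform's exon can sit inside another's
intron), CDS sub-intervals for a configurable fraction of transcripts, one
guaranteed intron ≥ 10× the rescale cap, and counts from a negative
binomial (dispersion 0.3, lognormal per-transcript means) with a
gene-level lognormal fold-change between two groups of four samples
("AD" vs "control"). The first gene always has ≥ 6 isoforms when the
configured range allows, so top-5 selection is a strict subset. A truth
record (expected rank order, intron coordinates, gap-map breakpoints,
fault list) is written alongside so tests compare against generator
bookkeeping rather than the code under test. Optionally the last genes are
given overlapping exons to exercise fault-skipping in batch mode; their
truth entries for introns/gap segments are not meaningful.

What it does **not** emulate: splice-site sequence content, read-level
noise, length biases, batch effects, or realistic genome-scale annotation
density. Passing tests therefore demonstrate the correctness of parsing,
normalization arithmetic, coordinate transforms and rendering contracts —
not robustness to the full messiness of public annotation releases.

Default problem sizes (3-gene fixtures; 200 random loci ≤ 50 kb for the
coordinate-map checks; 100 random matrices; 1000 random samples for box
statistics; a 50-gene batch) were chosen to exercise every code path at
desk scale while keeping the whole suite in seconds.

## Degenerate inputs and tie-breaks

Single-exon, single-transcript loci produce an identity map. An all-zero
sample or gene yields zero normalized values, not NaN. Empty
(transcript, group) cells yield an empty box with a warning. Ranking ties
are lexicographic. Batch mode treats per-gene failures as skips recorded
in the manifest; a pre-existing output with overwriting disabled is a
fatal, named error.

## Known limitations

- GTF only (no GFF3), local files only, no tabix indexing.
- One locus per figure; overlapping genes from different loci are not
  merged onto one axis.
- The interactive runtime is intentionally small: tooltips, legend
  toggling, zoom/pan — not a dashboard framework.
- PNG/PDF export approximates the SVG layout via matplotlib and is not
  guaranteed byte-deterministic across matplotlib versions (SVG and HTML
  are).
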