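"""Deterministic synthetic dataset generator.

Emulates the three inputs the pipeline needs — an ENSEMBL-dialect GTF, a
wide transcript-counts matrix and a sample metadata table — with the
structural features the method exercises: multi-transcript genes on both
strands, CDS sub-intervals of exons, at least one gene with enough
isoforms to exercise top-N selection, and at least one intron far longer
than the display rescale cap. Counts are negative-binomial with
per-transcript means and a gene-level fold-change between two sample
groups (a case/control design).

Every run with the same seed is byte-identical. A machine-readable truth
record accompanies the files so tests can check ranking, intron
derivation and gap-map construction against generator bookkeeping instead
of re-deriving them with the code under test.

Genes are laid out on alternating strands along a shared chromosome as a
"skeleton" of exon blocks; each transcript uses a random subset of blocks,
so exons of one isoform can fall inside another isoform's intron — the
case the shared rescaling map must handle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureTable, make_feature_table, write_gtf
from .errors import ConfigurationError

DEFAULT_GROUPS = ("AD", "control")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic dataset.

    Defaults mirror a small case/control isoform study: two groups of four
    samples, three genes, and one focal gene with at least six isoforms so
    a top-five selection is a strict subset.
    """

    n_genes: int = 3
    transcripts_per_gene: tuple[int, int] = (2, 7)
    exons_per_transcript: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (80, 600)
    long_intron_length: int = 5000   # >= 10x the default rescale cap (100)
    rescale_cap: float = 100.0
    cds_fraction: float = 0.7
    n_samples_per_group: int = 4
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    nb_mean_log_mu: float = 4.0      # lognormal base mean of NB counts
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.3       # NB size r = 1/dispersion
    fold_change_log_sigma: float = 0.6
    n_faulty_genes: int = 0          # trailing genes get overlapping exons
    seed: int = 1
    seqname: str = "chrS"
    source: str = "isoviz_sim"

    def validate(self) -> None:
        for name in ("transcripts_per_gene", "exons_per_transcript",
                     "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ConfigurationError("n_genes and n_samples_per_group must be >= 1")
        if not (0.0 <= self.cds_fraction <= 1.0):
            raise ConfigurationError("cds_fraction must be in [0, 1]")
        if self.n_faulty_genes >= self.n_genes:
            raise ConfigurationError("n_faulty_genes must leave at least one clean gene")


@dataclass
class FixtureTruth:
    """Generator bookkeeping used as an independent oracle in tests."""

    rank_by_mean_count: dict = field(default_factory=dict)   # gene -> [tx...]
    introns: dict = field(default_factory=dict)              # tx -> [[s, e]...]
    gap_segments: dict = field(default_factory=dict)         # gene -> [[gs, ge, ds, de]...]
    transcripts_of: dict = field(default_factory=dict)       # gene -> [tx...]
    strand_of: dict = field(default_factory=dict)            # gene -> strand
    faulty_genes: list = field(default_factory=list)
    focal_gene: str = ""
    config: dict = field(default_factory=dict)


def _gene_skeleton(rng: np.random.Generator, cfg: FixtureConfig, origin: int,
                   want_long_intron: bool) -> list[tuple[int, int]]:
    """Exon blocks of one gene along the chromosome, with introns between."""
    n_blocks = int(rng.integers(cfg.exons_per_transcript[0],
                                cfg.exons_per_transcript[1] + 1))
    blocks: list[tuple[int, int]] = []
    pos = origin
    long_at = int(rng.integers(0, max(n_blocks - 1, 1))) if n_blocks > 1 else -1
    for i in range(n_blocks):
        length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        blocks.append((pos, pos + length - 1))
        gap = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        if want_long_intron and i == long_at:
            gap = cfg.long_intron_length
        pos += length + gap
    return blocks


def _segments_from_union(blocks: list[tuple[int, int]], cap: float) -> list[list[float]]:
    """Expected gap-map segments from the union blocks (simple arithmetic)."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    segs: list[list[float]] = []
    disp = 0.0
    prev = None
    for s, e in merged:
        if prev is not None and s > prev + 1:
            gap = s - prev - 1
            d = min(float(gap), cap)
            segs.append([prev + 1, s - 1, disp + 1, disp + d])
            disp += d
        length = e - s + 1
        segs.append([s, e, disp + 1, disp + length])
        disp += length
        prev = e
    return segs


def simulate_dataset(cfg: FixtureConfig | None = None):
    """Build the dataset in memory.

    Returns ``(annotation, wide_counts, metadata, truth)`` where
    *wide_counts* is a DataFrame with a ``transcript_id`` column plus one
    column per sample, and *metadata* maps samples to their group.
    """
    cfg = cfg or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = FixtureTruth(config=asdict(cfg))

    records: list[dict] = []
    tx_means: dict[str, np.ndarray] = {}   # per-transcript mean per group
    origin = 1000
    n_groups = len(cfg.group_labels)
    lo_tx, hi_tx = cfg.transcripts_per_gene
    faulty = set()

    for g in range(cfg.n_genes):
        gene_id = f"SIMG{g + 1:05d}"
        gene_name = f"GENE{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        n_tx = int(rng.integers(lo_tx, hi_tx + 1))
        if g == 0:
            # the focal gene: top-5 of >= 6 isoforms (when the range allows)
            n_tx = max(n_tx, min(6, hi_tx))
            truth.focal_gene = gene_id
        is_faulty = g >= cfg.n_genes - cfg.n_faulty_genes
        blocks = _gene_skeleton(rng, cfg, origin, want_long_intron=(g == 0))
        used_blocks: set[int] = set()
        fold = float(np.exp(rng.normal(0.0, cfg.fold_change_log_sigma)))
        tx_ids = []
        for t in range(n_tx):
            tx_id = f"SIMT{g + 1:03d}{t + 1:03d}"
            tx_name = f"{gene_name}-{t + 1:03d}"
            tx_ids.append(tx_id)
            n_ex = int(rng.integers(1, len(blocks) + 1)) if len(blocks) > 1 else 1
            chosen = sorted(rng.choice(len(blocks), size=n_ex, replace=False).tolist())
            if t == 0:  # first isoform uses the full skeleton: union is covered
                chosen = list(range(len(blocks)))
            used_blocks.update(chosen)
            exons = [blocks[i] for i in chosen]
            if is_faulty and t == 0 and len(exons) >= 2:
                # inject overlapping exons: stretch the first exon into the next
                exons[0] = (exons[0][0], exons[1][0] + 5)
            base = dict(seqname=cfg.seqname, source=cfg.source, strand=strand,
                        gene_id=gene_id, gene_name=gene_name,
                        transcript_id=tx_id, transcript_name=tx_name,
                        transcript_biotype="protein_coding", exon_number=None)
            for s, e in exons:
                records.append(dict(base, feature_kind="exon", start=s, end=e))
            coding = rng.random() < cfg.cds_fraction and not is_faulty
            if coding:
                cds_lo = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
                cds_hi = exons[-1][1] - (exons[-1][1] - exons[-1][0]) // 2
                if cds_lo <= cds_hi:
                    for s, e in exons:
                        cs, ce = max(s, cds_lo), min(e, cds_hi)
                        if cs <= ce:
                            records.append(dict(base, feature_kind="CDS",
                                                start=cs, end=ce))
            else:
                base["transcript_biotype"] = "lncRNA"
                for r in records[-len(exons):]:
                    r["transcript_biotype"] = "lncRNA"
            # truth: introns from sorted exons
            introns = []
            if not (is_faulty and t == 0):
                ex_sorted = sorted(exons)
                for (s1, e1), (s2, e2) in zip(ex_sorted, ex_sorted[1:]):
                    if s2 > e1 + 1:
                        introns.append([e1 + 1, s2 - 1])
            truth.introns[tx_id] = introns
            # expression model: lognormal base mean, gene fold between groups
            base_mean = float(np.exp(rng.normal(cfg.nb_mean_log_mu,
                                                cfg.nb_mean_log_sigma)))
            means = np.array([base_mean * (fold if gi == 0 else 1.0)
                              for gi in range(n_groups)])
            tx_means[tx_id] = means
        truth.transcripts_of[gene_id] = tx_ids
        truth.strand_of[gene_id] = strand
        if is_faulty:
            faulty.add(gene_id)
        union_blocks = [blocks[i] for i in sorted(used_blocks)]
        truth.gap_segments[gene_id] = _segments_from_union(union_blocks,
                                                           cfg.rescale_cap)
        origin = max(e for _, e in blocks) + 10_000

    truth.faulty_genes = sorted(faulty)

    # counts: NB with size r = 1/dispersion, p = r / (r + mean)
    samples = [f"{g}_{i + 1}" for g in cfg.group_labels
               for i in range(cfg.n_samples_per_group)]
    sample_group = {s: s.rsplit("_", 1)[0] for s in samples}
    all_tx = sorted(tx_means)
    r_size = 1.0 / cfg.nb_dispersion
    counts = np.zeros((len(all_tx), len(samples)), dtype=np.int64)
    for i, tx in enumerate(all_tx):
        for j, s in enumerate(samples):
            gi = list(cfg.group_labels).index(sample_group[s])
            m = tx_means[tx][gi]
            p = r_size / (r_size + m)
            counts[i, j] = rng.negative_binomial(r_size, p)
    wide = pd.DataFrame(counts, columns=samples)
    wide.insert(0, "transcript_id", all_tx)

    # truth ranking: brute-force mean raw count, descending, lexicographic ties
    mean_counts = wide.set_index("transcript_id").mean(axis=1)
    for gene_id, tx_ids in truth.transcripts_of.items():
        order = sorted(tx_ids, key=lambda t: (-mean_counts[t], t))
        truth.rank_by_mean_count[gene_id] = order

    metadata = pd.DataFrame(
        {"sample_id": samples, "condition": [sample_group[s] for s in samples]}
    )
    annotation = make_feature_table(records, {"generator": "isoviz.simulate"})
    return annotation, wide, metadata, truth


def generate(cfg: FixtureConfig | None = None, out_dir: str | Path = ".") -> dict:
    """Write the GTF, counts CSV, metadata CSV and truth JSON to *out_dir*.

    Returns a dict of the four paths. Same seed, same bytes.
    """
    cfg = cfg or FixtureConfig()
    annotation, wide, metadata, truth = simulate_dataset(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "counts": out / "counts.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.json",
    }
    write_gtf(annotation, paths["gtf"])
    wide.to_csv(paths["counts"], index=False)
    metadata.to_csv(paths["metadata"], index=False)
    paths["truth"].write_text(
        json.dumps(asdict(truth), indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {k: str(v) for k, v in paths.items()}
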