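"""Synthetic nascent-transcription (NET-seq-geometry) read simulator.

Generates a toy genome with gene models and enhancers, then samples aligned
single-end reads whose 5' ends mark nascent-RNA 3' ends — the single-base
footprint of engaged RNA polymerase II.  Every molecule is recorded in a
ground-truth table so the read-level filters and downstream metrics can be
validated exactly.

Per-gene signal is a mixture of
  * a Gaussian promoter-proximal pause peak downstream of the TSS,
  * a uniform elongation signal over the gene body, multiplied inside exons
    by an exon-boost factor (exon-boundary pausing),
  * a divergent antisense initiation peak upstream of the TSS on the
    opposite strand.
Enhancers emit bidirectional positions uniformly over their span.  Library
artifacts are planted with known truth: splicing-intermediate reads exactly
at the 3'-terminal nucleotide of each exon and intron, PCR duplicates as
Poisson-distributed identical copies sharing a UMI, and RT-mispriming reads
at random genomic positions whose adjacent genomic sequence is made to match
the RT-primer prefix (so a sequence-based mispriming filter can find them).

Counts are Poisson; peak shapes are Gaussians rounded to integer
coordinates.  All randomness flows from one seed; outputs are byte-identical
across runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .annotation import (
    GeneModel,
    GenomeModel,
    Region,
    derive_introns,
    terminal_nucleotides,
    write_bed,
    write_chrom_sizes,
    write_gtf,
)

__all__ = [
    "GeneTruth",
    "EnhancerTruth",
    "SimulationTruth",
    "PRESETS",
    "build_toy_genome",
    "simulate_reads",
    "simulate",
    "expected_gene_molecules",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SQRT_2PI = math.sqrt(2.0 * math.pi)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class GeneTruth:
    """Programmed signal parameters for one gene.

    Rates are expected molecule counts: ``pause_height`` is the expected
    3'-end count at the pause-peak mode (total peak mass is
    ``pause_height * sqrt(2*pi) * pause_sd``); ``body_rate`` is the expected
    count per bp over the gene body.
    """

    pause_offset: float = 50.0  # bp downstream of TSS
    pause_height: float = 10.0  # expected count at the peak mode
    pause_sd: float = 30.0  # bp
    body_rate: float = 0.1  # expected count per bp
    body_start_offset: int = 300  # bp downstream of TSS where body signal begins
    antisense_height: float = 2.0
    antisense_offset: float = 150.0  # bp upstream of TSS, opposite strand
    antisense_sd: float = 40.0
    exon_boost: float = 1.5  # multiplier on body_rate inside exons
    intermediates_per_terminal: float = 2.0


@dataclass
class EnhancerTruth:
    rate: float = 0.02  # expected count per bp per strand


@dataclass
class SimulationTruth:
    """Programmed parameters for a whole simulated library."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    enhancers: dict[str, EnhancerTruth] = field(default_factory=dict)
    pcr_duplication_mean: float = 2.0
    mispriming_fraction: float = 0.05
    umi_length: int = 8
    read_length: int = 30
    primer: str = "GATCGG"
    polarity: str = "antisense"  # read aligns antisense to the transcript
    seed: int = 0


# Qualitative profile classes: broad elongation-factor-style signal
# (total / spt6 / ssrp1), a sharp initiation-factor peak with little body
# signal (tfiid), and a silent negative control (med14).
PRESETS: dict[str, dict] = {
    "total": {},
    "spt6": {"pause_height": 5.0, "pause_sd": 80.0, "body_rate": 0.12},
    "ssrp1": {"pause_height": 6.0, "pause_sd": 60.0, "body_rate": 0.10},
    "tfiid": {"pause_height": 15.0, "pause_sd": 8.0, "body_rate": 0.005,
              "antisense_height": 1.0},
    "med14": {"pause_height": 0.0, "pause_sd": 8.0, "body_rate": 0.0,
              "antisense_height": 0.0, "intermediates_per_terminal": 0.0},
}


class PackingError(RuntimeError):
    """Requested features do not fit on the toy genome."""


def build_toy_genome(
    n_chroms: int = 2,
    chrom_len: int = 150_000,
    n_genes: int = 10,
    n_enhancers: int = 8,
    seed: int = 0,
    preset: str = "total",
    gene_params: dict | None = None,
    enhancer_rate: float | None = None,
    super_rate: float | None = None,
    min_gene_gap: int = 6000,
    enhancer_gene_gap: int = 3000,
    n_proximal_enhancers: int | None = None,
    vary_genes: bool = True,
    margin: int = 500,
) -> tuple[GenomeModel, SimulationTruth]:
    """Lay out a non-overlapping toy genome and its programmed truth.

    Genes (3-8 exons, alternating strands) are separated by at least
    ``min_gene_gap`` so the promoter-clash filter retains them all; enhancers
    follow the genes on each chromosome, all but ``n_proximal_enhancers`` of
    them at least ``enhancer_gene_gap`` from any gene.  Enhancer classes
    alternate within each chromosome between 'typical' and 'super' (the
    latter larger and, by default, five-fold more transcribed).  Raises :class:`PackingError` if the
    requested features do not fit.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_sizes = {c: chrom_len for c in chroms}
    cursors = {c: margin for c in chroms}
    base = {**asdict(GeneTruth()), **PRESETS[preset], **(gene_params or {})}
    if enhancer_rate is None:
        enhancer_rate = 0.0 if preset == "med14" else 0.02
    if super_rate is None:
        super_rate = 0.0 if preset == "med14" else 0.10
    if n_proximal_enhancers is None:
        n_proximal_enhancers = n_enhancers // 4

    genes: list[GeneModel] = []
    gene_truth: dict[str, GeneTruth] = {}
    for i in range(n_genes):
        chrom = chroms[i % n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 9))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(300, 901, size=n_exons - 1)
        start = cursors[chrom] + min_gene_gap + int(rng.integers(0, 2001))
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        end = pos
        if end > chrom_len - margin:
            raise PackingError(
                f"infeasible packing: gene {i} would end at {end} on {chrom} "
                f"(length {chrom_len})"
            )
        gid = f"g{i + 1:03d}"
        genes.append(GeneModel(gid, chrom, strand, start, end, exons))
        cursors[chrom] = end
        gt = GeneTruth(**base)
        if vary_genes:
            gt.pause_height *= float(rng.uniform(0.5, 2.0))
            gt.body_rate *= float(rng.uniform(0.5, 2.0))
        gene_truth[gid] = gt

    enhancers: list[Region] = []
    enh_truth: dict[str, EnhancerTruth] = {}
    n_prox_placed = 0
    for j in range(n_enhancers):
        chrom = chroms[j % n_chroms]
        is_super = (j // n_chroms) % 2 == 1  # alternate classes within each chromosome
        length = int(rng.integers(3000, 8001) if is_super else rng.integers(500, 1501))
        if n_prox_placed < n_proximal_enhancers:
            gap = int(rng.integers(300, 1500))
            n_prox_placed += 1
        else:
            gap = enhancer_gene_gap + int(rng.integers(0, 2001))
        start = cursors[chrom] + gap
        end = start + length
        if end > chrom_len - margin:
            raise PackingError(
                f"infeasible packing: enhancer {j} would end at {end} on {chrom}"
            )
        label = ("super" if is_super else "typical") + f":e{j + 1:03d}"
        enhancers.append(Region(chrom, start, end, ".", label))
        enh_truth[label] = EnhancerTruth(rate=super_rate if is_super else enhancer_rate)
        cursors[chrom] = end

    model = GenomeModel(chrom_sizes, genes, enhancers)
    model.validate()
    truth = SimulationTruth(genes=gene_truth, enhancers=enh_truth, seed=seed)
    return model, truth


def expected_gene_molecules(gene: GeneModel, gt: GeneTruth) -> float:
    """Expected number of unique molecules the simulator programs for a gene."""
    pause = gt.pause_height * SQRT_2PI * gt.pause_sd
    anti = gt.antisense_height * SQRT_2PI * gt.antisense_sd
    body = 0.0
    if gt.body_rate > 0 and gene.length > gt.body_start_offset:
        body_len = gene.length - gt.body_start_offset
        exon_bp = _exon_bp_in_body(gene, gt.body_start_offset)
        body = gt.body_rate * ((body_len - exon_bp) + gt.exon_boost * exon_bp)
    n_terms = 2 * len(gene.exons) - 1  # exons + introns
    inter = gt.intermediates_per_terminal * n_terms
    return pause + anti + body + inter


def _oriented_to_genomic(gene: GeneModel, offsets: np.ndarray) -> np.ndarray:
    """Map transcription-direction offsets from the TSS to genomic coordinates."""
    if gene.strand == "+":
        return gene.tss + offsets
    return gene.tss - offsets


def _exon_mask(gene: GeneModel) -> np.ndarray:
    mask = np.zeros(gene.length, dtype=bool)
    for s, e in gene.exons_genomic():
        mask[s - gene.start : e - gene.start] = True
    return mask


def _exon_bp_in_body(gene: GeneModel, body_start_offset: int) -> int:
    mask = _exon_mask(gene)
    if gene.strand == "-":
        mask = mask[::-1]
    return int(mask[body_start_offset:].sum())


def _align_strand(tstrand: str, polarity: str) -> str:
    if polarity == "antisense":
        return "-" if tstrand == "+" else "+"
    return tstrand


def _context_window(pos: int, tstrand: str, polarity: str, read_len: int, k: int):
    """Genomic window of the k bases 3'-adjacent (in read orientation) to the
    aligned 3' end of the read whose 5' end sits at ``pos``."""
    a = _align_strand(tstrand, polarity)
    if a == "+":
        return pos + read_len, pos + read_len + k, "+"
    return pos - read_len + 1 - k, pos - read_len + 1, "-"


def simulate_reads(
    model: GenomeModel,
    truth: SimulationTruth,
    outdir: str,
    write_reference: bool = True,
) -> dict[str, str]:
    """Sample molecules, apply library artifacts, and write all outputs.

    Writes ``reads.sam`` (coordinate-sorted, UMIs in both the read name and
    the RX tag), ``truth.tsv``, ``genes.gtf``, ``enhancers.bed``,
    ``super_enhancers.bed``, ``chrom.sizes`` and, unless disabled,
    ``reference.fa``.  Returns a dict of output paths.
    """
    import os

    rng = np.random.default_rng(truth.seed)
    L, k = truth.read_length, len(truth.primer)
    edge = L + k + 1  # keep alignments and primer contexts inside the chromosome

    # molecules: (chrom, pos, tstrand, source_id, category)
    molecules: list[tuple[str, int, str, str, str]] = []

    for gene in sorted(model.genes, key=lambda g: g.gene_id):
        gt = truth.genes[gene.gene_id]
        clen = model.chrom_sizes[gene.chrom]

        def keep(p: np.ndarray) -> np.ndarray:
            return p[(p >= edge) & (p < clen - edge)]

        # promoter-proximal pause peak
        if gt.pause_height > 0 and gt.pause_sd > 0:
            n = rng.poisson(gt.pause_height * SQRT_2PI * gt.pause_sd)
            off = np.rint(rng.normal(gt.pause_offset, gt.pause_sd, size=n)).astype(int)
            for p in keep(_oriented_to_genomic(gene, off)):
                molecules.append((gene.chrom, int(p), gene.strand, gene.gene_id, "pause"))
        # gene body with exon boost
        if gt.body_rate > 0 and gene.length > gt.body_start_offset:
            mask = _exon_mask(gene)
            if gene.strand == "-":
                mask = mask[::-1]
            rates = np.full(gene.length, gt.body_rate)
            rates[mask] *= gt.exon_boost
            rates[: gt.body_start_offset] = 0.0
            counts = rng.poisson(rates)
            off = np.repeat(np.arange(gene.length), counts)
            for p in keep(_oriented_to_genomic(gene, off)):
                molecules.append((gene.chrom, int(p), gene.strand, gene.gene_id, "body"))
        # divergent antisense initiation
        if gt.antisense_height > 0 and gt.antisense_sd > 0:
            n = rng.poisson(gt.antisense_height * SQRT_2PI * gt.antisense_sd)
            off = -np.rint(
                rng.normal(gt.antisense_offset, gt.antisense_sd, size=n)
            ).astype(int)
            anti = "-" if gene.strand == "+" else "+"
            for p in keep(_oriented_to_genomic(gene, off)):
                molecules.append((gene.chrom, int(p), anti, gene.gene_id, "antisense"))
        # splicing intermediates exactly at terminal nucleotides
        if gt.intermediates_per_terminal > 0:
            for chrom, coord, strand in sorted(terminal_nucleotides([gene])):
                for _ in range(rng.poisson(gt.intermediates_per_terminal)):
                    molecules.append((chrom, coord, strand, gene.gene_id, "intermediate"))

    for enh in sorted(model.enhancers, key=lambda r: r.label):
        et = truth.enhancers[enh.label]
        if et.rate <= 0:
            continue
        clen = model.chrom_sizes[enh.chrom]
        for strand in ("+", "-"):
            counts = rng.poisson(et.rate, size=enh.length)
            pos = enh.start + np.repeat(np.arange(enh.length), counts)
            pos = pos[(pos >= edge) & (pos < clen - edge)]
            for p in pos:
                molecules.append((enh.chrom, int(p), strand, enh.label, "enhancer"))

    occupied = {(c, p, s) for c, p, s, _, _ in molecules}

    # RT-mispriming artifacts at random positions not occupied by a genuine
    # molecule; their genomic context will be made to match the primer.
    n_mis = rng.poisson(truth.mispriming_fraction * len(molecules))
    chrom_names = sorted(model.chrom_sizes)
    planted: dict[str, set[int]] = {c: set() for c in chrom_names}
    misprimed: list[tuple[str, int, str, str, str]] = []
    attempts = 0
    while len(misprimed) < n_mis and attempts < 50 * max(n_mis, 1):
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        clen = model.chrom_sizes[chrom]
        p = int(rng.integers(edge, clen - edge))
        s = "+" if rng.random() < 0.5 else "-"
        if (chrom, p, s) in occupied:
            continue
        ws, we, _ = _context_window(p, s, truth.polarity, L, k)
        # never overlap another planted context: orientations may conflict
        if any(i in planted[chrom] for i in range(ws, we)):
            continue
        misprimed.append((chrom, p, s, ".", "misprimed"))
        occupied.add((chrom, p, s))
        planted[chrom].update(range(ws, we))
    molecules.extend(misprimed)

    # reference sequence: random bases, primer contexts planted for misprimed
    # molecules, accidental primer matches at genuine contexts scrubbed
    ref = {
        c: rng.integers(0, 4, size=model.chrom_sizes[c]).astype(np.uint8)
        for c in chrom_names
    }
    base_to_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp_idx = np.array([3, 2, 1, 0], dtype=np.uint8)
    primer_idx = np.array([base_to_idx[b] for b in truth.primer], dtype=np.uint8)

    for chrom, p, s, _, _ in misprimed:
        ws, we, orient = _context_window(p, s, truth.polarity, L, k)
        ref[chrom][ws:we] = primer_idx if orient == "+" else comp_idx[primer_idx][::-1]

    genuine_keys = sorted({(c, p, s) for c, p, s, _, cat in molecules if cat != "misprimed"})
    for _ in range(6):  # fixpoint: scrubbing one window cannot be undone by another
        n_fixed = 0
        for chrom, p, s in genuine_keys:
            ws, we, orient = _context_window(p, s, truth.polarity, L, k)
            win = ref[chrom][ws:we]
            ctx = win if orient == "+" else comp_idx[win][::-1]
            if np.array_equal(ctx, primer_idx):
                for i in range(ws, we):
                    if i not in planted[chrom]:
                        ref[chrom][i] = (ref[chrom][i] + 1) % 4
                        n_fixed += 1
                        break
        if n_fixed == 0:
            break

    # UMIs: unique within each (chrom, pos, strand) so deduplication is exact
    by_key: dict[tuple[str, int, str], list[int]] = {}
    for idx, (c, p, s, _, _) in enumerate(molecules):
        by_key.setdefault((c, p, s), []).append(idx)
    umis = [""] * len(molecules)
    for key in sorted(by_key):
        seen: set[str] = set()
        for idx in by_key[key]:
            while True:
                u = "".join(
                    "ACGT"[b] for b in rng.integers(0, 4, size=truth.umi_length)
                )
                if u not in seen:
                    seen.add(u)
                    break
            umis[idx] = u

    n_copies = 1 + rng.poisson(truth.pcr_duplication_mean, size=len(molecules))

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sam": os.path.join(outdir, "reads.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "gtf": os.path.join(outdir, "genes.gtf"),
        "enhancers": os.path.join(outdir, "enhancers.bed"),
        "super_enhancers": os.path.join(outdir, "super_enhancers.bed"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "reference": os.path.join(outdir, "reference.fa"),
    }

    records = []
    for idx, (chrom, p, s, src, cat) in enumerate(molecules):
        a = _align_strand(s, truth.polarity)
        ref_start = p if a == "+" else p - L + 1
        for copy in range(int(n_copies[idx])):
            qname = f"m{idx:07d}c{copy}_UMI:{umis[idx]}"
            records.append((chrom, ref_start, a, qname, umis[idx]))
    records.sort(key=lambda r: (r[0], r[1], r[3]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": model.chrom_sizes[c]} for c in chrom_names],
    }
    tid = {c: i for i, c in enumerate(chrom_names)}
    idx_to_base = np.frombuffer(b"ACGT", dtype="S1")
    with pysam.AlignmentFile(paths["sam"], "w", header=header) as sam:
        for chrom, ref_start, a, qname, umi in records:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = qname
            seg.flag = 0 if a == "+" else 16
            seg.reference_id = tid[chrom]
            seg.reference_start = ref_start
            seg.mapping_quality = 60
            seg.cigarstring = f"{L}M"
            seq = idx_to_base[ref[chrom][ref_start : ref_start + L]].tobytes().decode()
            seg.query_sequence = seq if a == "+" else _revcomp(seq)
            seg.set_tag("RX", umi)
            sam.write(seg)

    pd.DataFrame(
        {
            "molecule_id": [f"m{idx:07d}" for idx in range(len(molecules))],
            "chrom": [m[0] for m in molecules],
            "pos": [m[1] for m in molecules],
            "transcript_strand": [m[2] for m in molecules],
            "align_strand": [
                _align_strand(m[2], truth.polarity) for m in molecules
            ],
            "umi": umis,
            "source": [m[3] for m in molecules],
            "category": [m[4] for m in molecules],
            "n_copies": n_copies,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)

    write_gtf(model.genes, paths["gtf"])
    write_bed(
        [r for r in model.enhancers if r.label.startswith("typical")],
        paths["enhancers"],
    )
    write_bed(
        [r for r in model.enhancers if r.label.startswith("super")],
        paths["super_enhancers"],
    )
    write_chrom_sizes(model.chrom_sizes, paths["chrom_sizes"])

    if write_reference:
        with open(paths["reference"], "w") as fh:
            for c in chrom_names:
                fh.write(f">{c}\n")
                seq = idx_to_base[ref[c]].tobytes().decode()
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    else:
        paths.pop("reference")
    return paths


def simulate(
    outdir: str,
    preset: str = "total",
    seed: int = 0,
    **genome_kwargs,
) -> tuple[GenomeModel, SimulationTruth, dict[str, str]]:
    """Build a toy genome under ``preset`` and write a full simulated library."""
    model, truth = build_toy_genome(seed=seed, preset=preset, **genome_kwargs)
    paths = simulate_reads(model, truth, outdir)
    return model, truth, paths
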