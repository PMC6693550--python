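"""Genome annotation model and interval derivation.

All internal coordinates are 0-based half-open on the genomic axis; GTF input
is converted on read (1-based inclusive -> 0-based half-open) and back on
write.  BED coordinates pass through unchanged.

The interval classes derived here drive the whole analysis: introns, the
3'-terminal nucleotides of exons and introns (where splicing intermediates
accumulate), internal exons for exon/intron coverage comparisons, the
promoter-clash-free gene set used for pausing analysis, and distal enhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "Region",
    "GeneModel",
    "GenomeModel",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "derive_introns",
    "terminal_nucleotides",
    "internal_exons",
    "promoter_clash_filter",
    "select_distal_enhancers",
]


class AnnotationError(ValueError):
    """Raised when annotation input fails validation."""


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single-transcript gene model.

    ``exons`` are half-open genomic intervals stored in transcription order:
    ascending start for '+' genes, descending for '-' genes.  ``tss``/``tes``
    are 0-based coordinates of the first/last transcribed base.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene with zero exons")
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if e0 > s1:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        for s, e in ex:
            if s < self.start or e > self.end:
                raise AnnotationError(f"{self.gene_id}: exon outside gene span")
        if ex[0][0] != self.start or ex[-1][1] != self.end:
            raise AnnotationError(f"{self.gene_id}: exons do not reach gene ends")
        # normalize to transcription order
        self.exons = ex if self.strand == "+" else ex[::-1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted on the genomic axis regardless of strand."""
        return sorted(self.exons)


@dataclass
class GenomeModel:
    """Chromosome sizes, gene models and (optionally) enhancer intervals."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    enhancers: list[Region] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise AnnotationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.chrom]):
                raise AnnotationError(f"{g.gene_id}: gene outside chromosome bounds")
        for r in self.enhancers:
            if r.chrom not in self.chrom_sizes:
                raise AnnotationError(f"enhancer {r.label}: unknown chromosome {r.chrom}")
            if r.end > self.chrom_sizes[r.chrom]:
                raise AnnotationError(f"enhancer {r.label}: outside chromosome bounds")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())


# ---------------------------------------------------------------------------
# I/O


def read_gtf(path: str) -> list[GeneModel]:
    """Parse a GTF into one :class:`GeneModel` per gene.

    One transcript is chosen per gene: the transcript with the longest genomic
    span, ties broken by lexicographically smallest transcript_id.  The gene
    span is the span of the chosen transcript's exons.
    """
    _pre_validate_gtf(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            path,
            ":memory:",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        candidates = []
        for tf in db.children(gf, featuretype="transcript"):
            span = tf.end - tf.start + 1
            candidates.append((-span, tf.id, tf))
        if candidates:
            _, _, chosen = min(candidates)
            exon_parent = chosen
        else:  # exon records attached directly to the gene
            exon_parent = gf
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(exon_parent, featuretype="exon")
        )
        if not exons:
            raise AnnotationError(f"gene {gf.id}: gene with zero exons")
        merged = _merge_intervals(exons)
        genes.append(
            GeneModel(
                gene_id=gf.id,
                chrom=gf.seqid,
                strand=gf.strand,
                start=merged[0][0],
                end=merged[-1][1],
                exons=merged,
            )
        )
    return genes


def _pre_validate_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: bad coordinate range"
                )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def write_gtf(genes: list[GeneModel], path: str, source: str = "netprism") -> None:
    """Write gene/transcript/exon records, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            tid = f"{g.gene_id}.t1"
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
            for ftype, s, e in [("gene", g.start, g.end), ("transcript", g.start, g.end)]:
                fh.write(
                    f"{g.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for s, e in g.exons_genomic():
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str, label_class: str = "") -> list[Region]:
    """Read BED (>=3 columns); 4th column becomes the region name.

    ``label_class`` tags every region with an enhancer class (e.g. 'typical'
    or 'super'); it is stored in :attr:`Region.label` as ``class:name``
    when a name column is present, else ``class``.
    """
    out: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise AnnotationError(f"{path}: malformed BED line {lineno}")
            name = f[3] if len(f) > 3 else f"{path}:{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            label = f"{label_class}:{name}" if label_class else name
            out.append(Region(f[0], int(f[1]), int(f[2]), strand, label))
    return out


def write_bed(regions: list[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.label)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t0\t{r.strand}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


# ---------------------------------------------------------------------------
# Derived interval classes


def derive_introns(gene: GeneModel) -> list[Region]:
    """Maximal gaps between consecutive exons, in transcription order."""
    out = []
    ex = gene.exons_genomic()
    for i, ((_, e0), (s1, _)) in enumerate(zip(ex, ex[1:])):
        out.append(Region(gene.chrom, e0, s1, gene.strand, f"{gene.gene_id}.i{i + 1}"))
    return out if gene.strand == "+" else out[::-1]


def terminal_nucleotides(genes: list[GeneModel]) -> set[tuple[str, int, str]]:
    """3'-terminal (transcription-direction last) base of every exon and intron.

    These single coordinates are where splicing intermediates map exactly: the
    last exon base corresponds to a cleaved 5' splice site, the last intron
    base to the lariat branch intermediate.  For a '+' feature [s,e) the
    terminal base is e-1; for '-' it is s.
    """
    terms: set[tuple[str, int, str]] = set()
    for g in genes:
        feats = [(s, e) for s, e in g.exons_genomic()]
        feats += [(r.start, r.end) for r in derive_introns(g)]
        for s, e in feats:
            coord = e - 1 if g.strand == "+" else s
            terms.add((g.chrom, coord, g.strand))
    return terms


def internal_exons(gene: GeneModel) -> list[Region]:
    """Exons with the first and last (in transcription order) removed."""
    out = []
    for i, (s, e) in enumerate(gene.exons[1:-1], start=2):
        out.append(Region(gene.chrom, s, e, gene.strand, f"{gene.gene_id}.e{i}"))
    return out


def _upstream_window(
    gene: GeneModel, upstream_bp: int, chrom_len: int | None = None
) -> tuple[int, int]:
    """Half-open genomic window of ``upstream_bp`` bases 5' of the TSS."""
    if gene.strand == "+":
        lo, hi = gene.start - upstream_bp, gene.start
    else:
        lo, hi = gene.end, gene.end + upstream_bp
    lo = max(lo, 0)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return lo, hi


def promoter_clash_filter(
    genes: list[GeneModel],
    upstream_bp: int = 2500,
    chrom_sizes: dict[str, int] | None = None,
    mode: str = "body",
) -> list[GeneModel]:
    """Drop genes whose upstream promoter region is contaminated by another gene.

    A gene is retained iff no other gene intersects the ``upstream_bp`` window
    immediately 5' of its TSS.  ``mode='body'`` (default) tests intersection
    against the other gene's whole span; ``mode='tss'`` tests whether the
    other gene's TSS falls inside the window.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if mode not in ("body", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept = []
    for g in genes:
        clen = chrom_sizes.get(g.chrom) if chrom_sizes else None
        lo, hi = _upstream_window(g, upstream_bp, clen)
        clash = False
        for other in by_chrom[g.chrom]:
            if other is g:
                continue
            if mode == "body":
                if other.start < hi and other.end > lo:
                    clash = True
                    break
            else:
                if lo <= other.tss < hi:
                    clash = True
                    break
        if not clash and hi > lo:
            kept.append(g)
    return kept


def select_distal_enhancers(
    enhancers: list[Region],
    genes: list[GeneModel],
    window_bp: int = 2000,
) -> list[Region]:
    """Enhancers whose interval expanded by ``window_bp`` on each side hits no gene.

    The expression gate (keeping only enhancers above an RPKM threshold for
    Pol II) is a separate step applied downstream from signal, not here.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept = []
    for r in enhancers:
        lo, hi = r.start - window_bp, r.end + window_bp
        if any(g.start < hi and g.end > lo for g in by_chrom.get(r.chrom, [])):
            continue
        kept.append(r)
    return kept
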