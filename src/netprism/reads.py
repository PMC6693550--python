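"""Read-level filters for nascent-transcription libraries.

The fixed filter order is: UMI-based PCR-duplicate removal, RT-mispriming
removal, 3'-end extraction (read 5' end = nascent-RNA 3' end), and
splicing-intermediate removal at exon/intron terminal nucleotides.  A
:class:`FilterReport` records the count entering and leaving every stage.

The mispriming rule is sequence-based: a read is an RT artifact when the
genomic bases immediately 3'-adjacent to its aligned 3' end match the RT
primer prefix — the signature of the primer having annealed to genomic
sequence rather than to the ligated adapter.  The original pipelines leave
this rule inside external scripts, so it is an explicit, documented stand-in
here; without a reference sequence the stage is a no-op (optionally honouring
simulator truth tags for validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

__all__ = [
    "ReadRecord",
    "FilterReport",
    "read_alignments",
    "deduplicate",
    "filter_mispriming",
    "extract_three_prime",
    "filter_splicing_intermediates",
    "process_alignments",
]

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read reduced to what the filters need."""

    chrom: str
    align_strand: str  # '+' or '-'
    ref_start: int  # 0-based leftmost aligned base (soft clips excluded)
    ref_end: int  # half-open rightmost
    umi: str
    qname: str

    @property
    def five_prime_pos(self) -> int:
        return self.ref_start if self.align_strand == "+" else self.ref_end - 1


@dataclass
class FilterReport:
    """Audit trail across the filter chain; counts are non-increasing."""

    n_input: int = 0
    n_skipped_unaligned: int = 0  # unmapped/secondary/supplementary
    n_low_mapq: int = 0
    n_missing_umi: int = 0
    n_after_dedup: int = 0
    n_after_mispriming: int = 0
    n_after_intermediates: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_skipped_unaligned": self.n_skipped_unaligned,
            "n_low_mapq": self.n_low_mapq,
            "n_missing_umi": self.n_missing_umi,
            "n_after_dedup": self.n_after_dedup,
            "n_after_mispriming": self.n_after_mispriming,
            "n_after_intermediates": self.n_after_intermediates,
            "removed": dict(self.removed),
        }


def _umi_from_read(aln: pysam.AlignedSegment, umi_tag: str) -> str | None:
    if aln.has_tag(umi_tag):
        return str(aln.get_tag(umi_tag))
    name = aln.query_name or ""
    if "_UMI:" in name:
        return name.rsplit("_UMI:", 1)[1]
    return None


def read_alignments(
    path: str,
    umi_tag: str = "RX",
    mapq_min: int = 10,
    include_softclip: bool = False,
    report: FilterReport | None = None,
) -> Iterator[ReadRecord]:
    """Stream primary alignments from a SAM/BAM file as :class:`ReadRecord`.

    Unmapped, secondary and supplementary records are skipped (counted);
    multi-mapped reads below ``mapq_min`` are dropped; reads without a UMI in
    the tag or the ``_UMI:`` read-name suffix are dropped with a warning.
    With ``include_softclip`` the 5' position is extended to the unclipped
    read end.
    """
    rep = report if report is not None else FilterReport()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                rep.n_skipped_unaligned += 1
                continue
            rep.n_input += 1
            if aln.mapping_quality < mapq_min:
                rep.n_low_mapq += 1
                continue
            umi = _umi_from_read(aln, umi_tag)
            if umi is None:
                rep.n_missing_umi += 1
                logger.warning("read %s has no UMI; dropped", aln.query_name)
                continue
            start, end = aln.reference_start, aln.reference_end
            if include_softclip and aln.cigartuples:
                if aln.cigartuples[0][0] == 4:  # leading soft clip
                    start -= aln.cigartuples[0][1]
                if aln.cigartuples[-1][0] == 4:
                    end += aln.cigartuples[-1][1]
            yield ReadRecord(
                chrom=aln.reference_name,
                align_strand="-" if aln.is_reverse else "+",
                ref_start=start,
                ref_end=end,
                umi=umi,
                qname=aln.query_name,
            )


def deduplicate(
    reads: Iterable[ReadRecord], report: FilterReport | None = None
) -> list[ReadRecord]:
    """Collapse PCR duplicates: one representative per
    (chrom, 5'-position, alignment strand, UMI).

    The representative is the first read in coordinate order; ties broken by
    lexicographically smallest query name.
    """
    best: dict[tuple[str, int, str, str], ReadRecord] = {}
    n_in = 0
    for r in reads:
        n_in += 1
        key = (r.chrom, r.five_prime_pos, r.align_strand, r.umi)
        cur = best.get(key)
        if cur is None or (r.ref_start, r.qname) < (cur.ref_start, cur.qname):
            best[key] = r
    out = sorted(best.values(), key=lambda r: (r.chrom, r.ref_start, r.qname))
    if report is not None:
        report.n_after_dedup = len(out)
        report.removed["pcr_duplicates"] = n_in - len(out)
    return out


def filter_mispriming(
    reads: Iterable[ReadRecord],
    reference: "object | None" = None,
    primer_prefix: str = "",
    k: int = 6,
    truth_misprimed: set[tuple[str, int, str]] | None = None,
    report: FilterReport | None = None,
) -> list[ReadRecord]:
    """Remove RT-mispriming artifacts.

    With a ``reference`` (any mapping of chromosome name to indexable
    sequence, e.g. :class:`pyfaidx.Fasta` or :class:`pysam.FastaFile` via
    :func:`fasta_provider`), a read is removed iff the ``k`` genomic bases
    immediately 3'-adjacent to its aligned 3' end (in read orientation) equal
    the first ``k`` bases of ``primer_prefix``.  Without a reference the
    filter is a no-op, unless ``truth_misprimed`` supplies a simulator
    truth set of (chrom, 5'-pos, align_strand) keys (validation mode).
    """
    n_in = 0
    out: list[ReadRecord] = []
    prefix = primer_prefix[:k].upper()
    if reference is None and truth_misprimed is None:
        logger.info("mispriming filter: no reference sequence; stage is a no-op")
    for r in reads:
        n_in += 1
        remove = False
        if reference is not None and k > 0 and prefix:
            ctx = _adjacent_context(r, reference, k)
            remove = ctx == prefix
        elif truth_misprimed is not None:
            remove = (r.chrom, r.five_prime_pos, r.align_strand) in truth_misprimed
        if not remove:
            out.append(r)
    if report is not None:
        report.n_after_mispriming = len(out)
        report.removed["mispriming"] = n_in - len(out)
    return out


def _adjacent_context(r: ReadRecord, reference, k: int) -> str:
    try:
        seq = reference[r.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {r.chrom} absent from reference") from exc
    if r.align_strand == "+":
        ctx = str(seq[r.ref_end : r.ref_end + k])
        if len(ctx) < k:
            return ""  # runs off the chromosome: cannot match
        return ctx.upper()
    lo = r.ref_start - k
    if lo < 0:
        return ""
    return _revcomp(str(seq[lo : r.ref_start]).upper())


def extract_three_prime(
    read: ReadRecord, polarity: str = "antisense"
) -> tuple[str, int, str]:
    """Map a read to its nascent-RNA 3'-end position and transcript strand.

    The coordinate is the read's 5'-end genomic position (leftmost aligned
    base for '+' alignments, rightmost for '-').  Under the standard NET-seq
    geometry (``polarity='antisense'``) the sequencing read aligns antisense
    to the transcript, so the transcript strand is the opposite of the
    alignment strand; ``polarity='sense'`` keeps them equal.
    """
    if polarity not in ("antisense", "sense"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if polarity == "antisense":
        tstrand = "-" if read.align_strand == "+" else "+"
    else:
        tstrand = read.align_strand
    return (read.chrom, read.five_prime_pos, tstrand)


def filter_splicing_intermediates(
    positions: Iterable[tuple[str, int, str]],
    terminals: set[tuple[str, int, str]],
    report: FilterReport | None = None,
) -> list[tuple[str, int, str]]:
    """Drop 3'-end positions that fall exactly on an exon/intron terminal
    nucleotide (splicing intermediates), matched on the transcript strand."""
    n_in = 0
    out = []
    for pos in positions:
        n_in += 1
        if pos not in terminals:
            out.append(pos)
    if report is not None:
        report.n_after_intermediates = len(out)
        report.removed["splicing_intermediates"] = n_in - len(out)
    return out


def fasta_provider(path: str):
    """Open a FASTA file as a chromosome-name -> sequence mapping."""
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def process_alignments(
    path: str,
    terminals: set[tuple[str, int, str]],
    reference_path: str | None = None,
    primer_prefix: str = "",
    k: int = 6,
    polarity: str = "antisense",
    umi_tag: str = "RX",
    mapq_min: int = 10,
    truth_misprimed: set[tuple[str, int, str]] | None = None,
) -> tuple[list[tuple[str, int, str]], FilterReport]:
    """Run the full filter chain on a SAM/BAM file.

    Returns the retained (chrom, position, transcript_strand) 3'-end list and
    the per-stage :class:`FilterReport`.
    """
    report = FilterReport()
    stream = read_alignments(path, umi_tag=umi_tag, mapq_min=mapq_min, report=report)
    deduped = deduplicate(stream, report=report)
    reference = fasta_provider(reference_path) if reference_path else None
    kept = filter_mispriming(
        deduped,
        reference=reference,
        primer_prefix=primer_prefix,
        k=k,
        truth_misprimed=truth_misprimed,
        report=report,
    )
    positions = [extract_three_prime(r, polarity=polarity) for r in kept]
    retained = filter_splicing_intermediates(positions, terminals, report=report)
    return retained, report
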