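"""Per-gene and per-feature Pol II statistics.

Travelling ratio (TR): promoter-window mean density over gene-body mean
density, computed on sense-strand signal.  Windows are strand-oriented and
half-open: promoter [TSS-30, TSS+250) (280 bp), body [TSS+300, TES-200).
A high TR means polymerase accumulates at the promoter relative to the body,
i.e. stronger promoter-proximal pausing.  Uniform coverage gives TR = 1 by
construction (density mode); a raw-sums mode ratioing window totals is also
provided.

Also here: RPKM gating, exon/intron feature densities, and the sense /
antisense tag split around the TSS that quantifies divergent initiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel, Region
from .tracks import SignalTrack

__all__ = [
    "TRRecord",
    "DensityRecord",
    "oriented_window",
    "travelling_ratio",
    "tr_cumulative",
    "rpkm",
    "count_in_region",
    "filter_by_rpkm",
    "feature_density",
    "sense_antisense_split",
]

#: sentinel for genes whose body density is zero (TR undefined)
TR_UNDEFINED = float("nan")


@dataclass
class TRRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    tr: float  # NaN when undefined
    reason: str = ""  # non-empty when the gene was excluded or TR undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tr)


@dataclass
class DensityRecord:
    feature_id: str
    kind: str  # exon | intron | gene | enhancer
    length: int
    density: float
    rpkm: float = float("nan")


def oriented_window(anchor: int, strand: str, lo: int, hi: int) -> tuple[int, int]:
    """Genomic half-open window for transcription-direction offsets [lo, hi).

    Offset 0 is the anchor base itself; positive offsets run in the direction
    of transcription.
    """
    if strand == "+":
        return anchor + lo, anchor + hi
    return anchor - hi + 1, anchor - lo + 1


def _window_values(
    track: SignalTrack, chrom: str, strand: str, start: int, end: int
) -> np.ndarray:
    arr = track.get(chrom, strand)
    start, end = max(0, start), min(arr.size, end)
    if end <= start:
        return np.zeros(0)
    return arr[start:end]


def travelling_ratio(
    gene: GeneModel,
    track: SignalTrack,
    promoter: tuple[int, int] = (-30, 250),
    body_start: int = 300,
    body_end_offset: int = 200,
    mode: str = "density",
) -> TRRecord:
    """Travelling ratio of one gene from sense-strand coverage.

    ``mode='density'`` (canonical) ratios mean per-bp coverage of the two
    windows; ``mode='sums'`` ratios the raw window totals.  Genes shorter
    than ``body_start + body_end_offset`` are excluded with reason
    ``'too_short'``; zero body density yields a NaN TR with reason
    ``'zero_body'``.
    """
    if mode not in ("density", "sums"):
        raise ValueError(f"unknown mode {mode!r}")
    if gene.length <= body_start + body_end_offset:
        return TRRecord(gene.gene_id, TR_UNDEFINED, TR_UNDEFINED, TR_UNDEFINED,
                        reason="too_short")
    ps, pe = oriented_window(gene.tss, gene.strand, *promoter)
    bs, be = oriented_window(gene.tss, gene.strand, body_start,
                             gene.length - body_end_offset)
    pvals = _window_values(track, gene.chrom, gene.strand, ps, pe)
    bvals = _window_values(track, gene.chrom, gene.strand, bs, be)
    if pvals.size == 0 or bvals.size == 0:
        return TRRecord(gene.gene_id, TR_UNDEFINED, TR_UNDEFINED, TR_UNDEFINED,
                        reason="window_clipped_away")
    pstat = float(pvals.mean()) if mode == "density" else float(pvals.sum())
    bstat = float(bvals.mean()) if mode == "density" else float(bvals.sum())
    if bstat == 0.0:
        return TRRecord(gene.gene_id, pstat, bstat, TR_UNDEFINED, reason="zero_body")
    return TRRecord(gene.gene_id, pstat, bstat, pstat / bstat)


def tr_cumulative(trs: Iterable[TRRecord]) -> pd.DataFrame:
    """Empirical CDF over defined TRs: sorted (tr, fraction <= tr) pairs.

    Undefined TRs are excluded; their count is stored in
    ``df.attrs['n_undefined']``.
    """
    recs = list(trs)
    defined = sorted(r.tr for r in recs if r.defined)
    if not defined:
        raise ValueError("no defined travelling ratios")
    n = len(defined)
    df = pd.DataFrame(
        {"tr": defined, "fraction": (np.arange(1, n + 1) / n)}
    )
    df.attrs["n_undefined"] = len(recs) - n
    return df


def rpkm(count: float, length_bp: int, total_retained: int) -> float:
    """Reads per kilobase of feature per million retained reads."""
    if length_bp <= 0:
        raise ValueError("zero-length feature")
    if total_retained <= 0:
        raise ValueError("total_retained must be > 0")
    return count / ((length_bp / 1e3) * (total_retained / 1e6))


def count_in_region(
    track: SignalTrack, chrom: str, start: int, end: int, strand: str = "."
) -> float:
    """Total track mass in [start, end): one strand for '+'/'-', both for '.'."""
    if strand in ("+", "-"):
        return float(_window_values(track, chrom, strand, start, end).sum())
    return float(
        _window_values(track, chrom, "+", start, end).sum()
        + _window_values(track, chrom, "-", start, end).sum()
    )


def _feature_span(feature) -> tuple[str, int, int, str]:
    if isinstance(feature, GeneModel):
        return feature.chrom, feature.start, feature.end, feature.strand
    return feature.chrom, feature.start, feature.end, feature.strand


def filter_by_rpkm(
    features: list,
    track: SignalTrack,
    total_retained: int,
    threshold: float = 1.0,
) -> list:
    """Keep features with RPKM > threshold.

    Counting uses sense-strand positions for stranded features and both
    strands for unstranded ones (enhancers), on the unnormalized track.
    """
    kept = []
    for f in features:
        chrom, start, end, strand = _feature_span(f)
        count = count_in_region(track, chrom, start, end, strand)
        if rpkm(count, end - start, total_retained) > threshold:
            kept.append(f)
    return kept


def feature_density(
    features: list[Region], track: SignalTrack, kind: str = ""
) -> list[DensityRecord]:
    """Mean per-bp sense-strand coverage over each feature."""
    out = []
    for f in features:
        vals = _window_values(track, f.chrom, f.strand, f.start, f.end)
        density = float(vals.mean()) if vals.size else 0.0
        out.append(DensityRecord(f.label, kind or "feature", f.length, density))
    return out


def sense_antisense_split(
    positions: Iterable[tuple[str, int, str]],
    genes: list[GeneModel],
    window: tuple[int, int] = (-1000, 1000),
) -> pd.DataFrame:
    """Count sense vs antisense 3'-end tags in a strand-oriented TSS window.

    A position counts as sense when its transcript strand matches the gene
    strand, antisense otherwise; antisense tags report divergent initiation
    upstream of the promoter.
    """
    pos_list = list(positions)
    rows = []
    for g in genes:
        ws, we = oriented_window(g.tss, g.strand, *window)
        sense = anti = 0
        for chrom, p, s in pos_list:
            if chrom == g.chrom and ws <= p < we:
                if s == g.strand:
                    sense += 1
                else:
                    anti += 1
        rows.append({"gene_id": g.gene_id, "sense": sense, "antisense": anti})
    return pd.DataFrame(rows)
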