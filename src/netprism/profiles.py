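"""Anchored, strand-oriented occupancy matrices and metaplots.

A :class:`ProfileMatrix` stacks coverage windows around a set of anchors
(TSSs, splice sites, enhancer centres), orientation-flipped so that positive
offsets always point in the transcription direction.  Row filtering removes
artifact rows whose signal is concentrated in a very short span — the
signature of unannotated short non-coding RNAs sitting inside the window —
and metaplots summarise column means with confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, internal_exons
from .tracks import SignalTrack, smooth

__all__ = [
    "Anchor",
    "ProfileMatrix",
    "tss_anchors",
    "boundary_anchors",
    "enhancer_anchors",
    "build_matrix",
    "artifact_row_filter",
    "metaplot",
]


@dataclass(frozen=True)
class Anchor:
    region_id: str
    chrom: str
    coord: int  # 0-based anchor base
    strand: str  # orientation of the profile; '+' for unstranded anchors


@dataclass
class ProfileMatrix:
    anchors: list[Anchor]
    offsets: np.ndarray  # [-W, +W), transcription-direction bp
    values: np.ndarray  # anchors x offsets
    channel: str  # sense | antisense
    clipped_rows: list[int] = field(default_factory=list)

    @property
    def half_width(self) -> int:
        return int(-self.offsets[0])

    def subset(self, row_idx: np.ndarray) -> "ProfileMatrix":
        return ProfileMatrix(
            [self.anchors[i] for i in row_idx],
            self.offsets,
            self.values[row_idx],
            self.channel,
        )


def tss_anchors(genes: list[GeneModel]) -> list[Anchor]:
    return [Anchor(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]


def boundary_anchors(genes: list[GeneModel]) -> tuple[list[Anchor], list[Anchor]]:
    """3'SS and 5'SS anchors of internal exons.

    The 3'SS anchor is the transcription-direction first base of the exon
    (just downstream of the intron 3' splice site); the 5'SS anchor is its
    last base.  First and last exons are excluded.
    """
    three_ss, five_ss = [], []
    for g in genes:
        for r in internal_exons(g):
            if g.strand == "+":
                a3, a5 = r.start, r.end - 1
            else:
                a3, a5 = r.end - 1, r.start
            three_ss.append(Anchor(f"{r.label}.3ss", g.chrom, a3, g.strand))
            five_ss.append(Anchor(f"{r.label}.5ss", g.chrom, a5, g.strand))
    return three_ss, five_ss


def enhancer_anchors(enhancers) -> list[Anchor]:
    return [
        Anchor(r.label, r.chrom, (r.start + r.end) // 2, "+") for r in enhancers
    ]


def build_matrix(
    track: SignalTrack,
    anchors: list[Anchor],
    half_width: int = 1000,
    channel: str = "sense",
) -> ProfileMatrix:
    """Stack oriented coverage windows around each anchor.

    Row r, column j holds the coverage at ``anchor_r + oriented offset_j`` on
    the requested channel (sense = the anchor's strand, antisense = the
    opposite strand).  Windows clipped at chromosome bounds are zero-padded
    and the row index recorded in ``clipped_rows``.
    """
    if channel not in ("sense", "antisense"):
        raise ValueError(f"unknown channel {channel!r}")
    offsets = np.arange(-half_width, half_width)
    values = np.zeros((len(anchors), offsets.size))
    clipped = []
    for i, a in enumerate(anchors):
        strand = a.strand if channel == "sense" else ("-" if a.strand == "+" else "+")
        arr = track.get(a.chrom, strand)
        if a.strand == "+":
            lo, hi = a.coord - half_width, a.coord + half_width
        else:
            lo, hi = a.coord - half_width + 1, a.coord + half_width + 1
        clo, chi = max(0, lo), min(arr.size, hi)
        if clo > lo or chi < hi:
            clipped.append(i)
        row = np.zeros(offsets.size)
        row[clo - lo : clo - lo + (chi - clo)] = arr[clo:chi]
        if a.strand == "-":
            row = row[::-1]
        values[i] = row
    return ProfileMatrix(list(anchors), offsets, values, channel, clipped)


def _max_window_sums(values: np.ndarray, span: int) -> np.ndarray:
    """Per-row maximum sum over any contiguous span of ``span`` columns."""
    span = min(span, values.shape[1])
    cs = np.cumsum(values, axis=1)
    cs = np.concatenate([np.zeros((values.shape[0], 1)), cs], axis=1)
    windows = cs[:, span:] - cs[:, :-span]
    return windows.max(axis=1)


def concentration(values: np.ndarray, span: int = 100) -> np.ndarray:
    """Fraction of each row's total mass inside its best ``span``-bp window
    (0 for zero-total rows)."""
    totals = values.sum(axis=1)
    best = _max_window_sums(values, span)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, best / np.where(totals > 0, totals, 1.0), 0.0)
    return frac


def artifact_row_filter(
    matrix: ProfileMatrix,
    span: int = 100,
    frac: float = 0.8,
    mode: str = "heuristic",
    height_quantile: float = 0.9,
    n_clusters: int = 6,
    seed: int = 0,
) -> tuple[ProfileMatrix, list[str]]:
    """Remove rows dominated by a concentrated high-occupancy spike.

    Such rows are the footprint of unannotated short non-coding RNAs inside
    the profile window, not of the gene's own polymerase.  ``heuristic`` mode
    (canonical, deterministic): a row is removed iff its best ``span``-bp
    window holds at least ``frac`` of its total mass AND its total is at or
    above the ``height_quantile`` quantile of the totals of non-concentrated
    rows (so re-applying the filter removes nothing further).  ``kmeans``
    mode clusters L1-normalized rows (k fixed, seeded) and removes whole
    clusters whose centroid satisfies the concentration rule.  Zero-total
    rows are never removed.
    """
    if matrix.values.shape[1] < span:
        raise ValueError("matrix is narrower than the concentration span")
    totals = matrix.values.sum(axis=1)
    conc = concentration(matrix.values, span)
    concentrated = (conc >= frac) & (totals > 0)
    if mode == "heuristic":
        clean_totals = totals[~concentrated]
        if clean_totals.size:
            threshold = float(np.quantile(clean_totals, height_quantile))
        else:
            threshold = float(np.quantile(totals, height_quantile))
        remove = concentrated & (totals >= threshold)
    elif mode == "kmeans":
        from sklearn.cluster import KMeans

        nz = totals > 0
        remove = np.zeros(len(totals), dtype=bool)
        if nz.sum() >= n_clusters:
            X = matrix.values[nz] / totals[nz, None]
            km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
            labels = km.fit_predict(X)
            bad = np.flatnonzero(
                concentration(km.cluster_centers_, span) >= frac
            )
            remove[np.flatnonzero(nz)[np.isin(labels, bad)]] = True
            clean_totals = totals[~remove]
            threshold = (
                float(np.quantile(clean_totals, height_quantile))
                if clean_totals.size
                else 0.0
            )
            remove &= totals >= threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep_idx = np.flatnonzero(~remove)
    removed_ids = [matrix.anchors[i].region_id for i in np.flatnonzero(remove)]
    return matrix.subset(keep_idx), removed_ids


def metaplot(
    matrix: ProfileMatrix,
    smooth_window: int = 10,
    ci: str = "normal95",
    n_boot: int = 1000,
    seed: int = 1729,
) -> "pd.DataFrame":
    """Column means with a 95% confidence band.

    Smoothing (centred moving average) is applied per row before averaging.
    ``ci='normal95'`` uses mean +/- 1.96 * sd / sqrt(n); ``'bootstrap95'``
    uses the percentile interval over ``n_boot`` row resamples (seeded);
    ``'none'`` returns the mean only.
    """
    import pandas as pd

    if ci not in ("none", "normal95", "bootstrap95"):
        raise ValueError(f"unknown ci {ci!r}")
    vals = matrix.values
    if smooth_window > 1 and vals.shape[0]:
        vals = np.vstack([smooth(row, smooth_window) for row in vals])
    mean = vals.mean(axis=0) if vals.shape[0] else np.zeros(matrix.offsets.size)
    df = pd.DataFrame({"offset": matrix.offsets, "mean": mean})
    if ci == "none" or vals.shape[0] < 2:
        df["lo"] = mean
        df["hi"] = mean
        return df
    if ci == "normal95":
        sem = vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
        df["lo"] = mean - 1.96 * sem
        df["hi"] = mean + 1.96 * sem
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, vals.shape[0], size=(n_boot, vals.shape[0]))
        boots = vals[idx].mean(axis=1)
        df["lo"] = np.quantile(boots, 0.025, axis=0)
        df["hi"] = np.quantile(boots, 0.975, axis=0)
    return df
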