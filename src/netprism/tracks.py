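"""Strand-specific single-base occupancy tracks.

A :class:`SignalTrack` holds one dense float array per chromosome per strand
at 1-bp resolution.  Tracks are built from filtered 3'-end positions, scaled
to 1x depth (RPGC: genome-wide mean per-base coverage of 1, both strands
summed, one global scale factor per library), optionally smoothed with a
centred moving average, and written as strand-separated bedGraph.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["SignalTrack", "build_track", "normalize_1x", "smooth",
           "write_bedgraph", "read_bedgraph"]


class TrackError(ValueError):
    pass


class SignalTrack:
    """Per-chromosome, per-strand single-base coverage arrays."""

    def __init__(self, chrom_sizes: dict[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.data: dict[str, dict[str, np.ndarray]] = {
            c: {"+": np.zeros(n), "-": np.zeros(n)} for c, n in chrom_sizes.items()
        }
        self.normalized = False
        self.scale_factor = 1.0
        self.n_positions = 0

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def total_mass(self) -> float:
        return float(
            sum(arr.sum() for d in self.data.values() for arr in d.values())
        )

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def copy(self) -> "SignalTrack":
        t = SignalTrack(self.chrom_sizes)
        for c in self.data:
            for s in "+-":
                t.data[c][s] = self.data[c][s].copy()
        t.normalized = self.normalized
        t.scale_factor = self.scale_factor
        t.n_positions = self.n_positions
        return t


def build_track(
    positions: Iterable[tuple[str, int, str]], chrom_sizes: dict[str, int]
) -> SignalTrack:
    """Histogram 3'-end positions into a track: one unit of mass per position."""
    track = SignalTrack(chrom_sizes)
    buckets: dict[tuple[str, str], list[int]] = {}
    n = 0
    for chrom, pos, strand in positions:
        if chrom not in chrom_sizes:
            raise TrackError(f"position ({chrom},{pos},{strand}): unknown chromosome")
        if not (0 <= pos < chrom_sizes[chrom]):
            raise TrackError(
                f"position ({chrom},{pos},{strand}) outside chromosome bounds"
            )
        buckets.setdefault((chrom, strand), []).append(pos)
        n += 1
    for (chrom, strand), pos_list in buckets.items():
        np.add.at(track.data[chrom][strand], np.asarray(pos_list), 1.0)
    track.n_positions = n
    return track


def normalize_1x(track: SignalTrack) -> SignalTrack:
    """Scale to 1x depth: every value times genome_size / n_positions.

    After scaling the genome-wide mean per-base coverage, summing both
    strands, is exactly 1.  Returns a new track.
    """
    if track.normalized:
        raise TrackError("track is already normalized")
    if track.n_positions == 0:
        raise TrackError("cannot normalize an empty track (0 positions)")
    out = track.copy()
    out.scale_factor = track.genome_size / track.n_positions
    for c in out.data:
        for s in "+-":
            out.data[c][s] *= out.scale_factor
    out.normalized = True
    return out


def smooth(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Centred moving average over ``[i - w//2, i - w//2 + w)``.

    At the edges the average runs over the in-bounds part of the window, so a
    constant array is returned unchanged.  A window longer than the array
    yields a constant array at the global mean.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return v.copy()
    if window > n:
        return np.full(n, v.mean())
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.clip(idx - window // 2, 0, n)
    hi = np.clip(idx - window // 2 + window, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def write_bedgraph(
    track: SignalTrack, path_plus: str, path_minus: str, signed: bool = False
) -> None:
    """Write strand-separated bedGraph, run-length merging equal values.

    Zero-valued runs are omitted.  With ``signed`` the minus-strand values
    are written negated (genome-browser convention).
    """
    for strand, path in (("+", path_plus), ("-", path_minus)):
        sign = -1.0 if (signed and strand == "-") else 1.0
        with open(path, "w") as fh:
            for chrom in sorted(track.chrom_sizes):
                arr = track.data[chrom][strand]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    val = arr[s]
                    if val != 0.0:
                        fh.write(
                            f"{chrom}\t{s}\t{e}\t{format(sign * val, '.17g')}\n"
                        )


def read_bedgraph(
    path_plus: str, path_minus: str, chrom_sizes: dict[str, int], signed: bool = False
) -> SignalTrack:
    """Inverse of :func:`write_bedgraph` (normalization state not recovered)."""
    track = SignalTrack(chrom_sizes)
    for strand, path in (("+", path_plus), ("-", path_minus)):
        sign = -1.0 if (signed and strand == "-") else 1.0
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split("\t")
                track.data[chrom][strand][int(s) : int(e)] = sign * float(v)
    track.n_positions = int(round(track.total_mass()))
    return track
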