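"""Transcription over distal vs super-enhancers.

Enhancer RNA production is bidirectional, so densities sum both strands.
The module builds an enhancer x library density table, computes
library-library Pearson correlation within an enhancer class, and compares
distal against super-enhancer densities with a two-sided Wilcoxon
(Mann-Whitney) rank-sum test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Region
from .tracks import SignalTrack

__all__ = [
    "enhancer_class",
    "resolve_enhancer_classes",
    "enhancer_density",
    "density_table",
    "library_correlation",
    "class_comparison",
]

logger = logging.getLogger(__name__)


def enhancer_class(region: Region) -> str:
    """'super' or 'distal' from the region label prefix ('super:...' wins)."""
    return "super" if region.label.startswith("super") else "distal"


def resolve_enhancer_classes(
    typical: list[Region], super_: list[Region]
) -> list[Region]:
    """Merge the two BED sets; overlaps are assigned to the super class."""
    out = list(super_)
    for r in typical:
        overlapping = any(
            r.chrom == s.chrom and r.start < s.end and r.end > s.start for s in super_
        )
        if overlapping:
            logger.info("enhancer %s overlaps a super-enhancer; assigned super", r.label)
            continue
        out.append(r)
    return out


def enhancer_density(
    track: SignalTrack, enhancers: list[Region], per_strand: bool = False
) -> pd.DataFrame:
    """Mean per-bp coverage per enhancer, both strands summed by default."""
    rows = []
    for r in enhancers:
        plus = float(track.get(r.chrom, "+")[r.start : r.end].sum())
        minus = float(track.get(r.chrom, "-")[r.start : r.end].sum())
        row = {
            "enhancer_id": r.label,
            "class": enhancer_class(r),
            "density": (plus + minus) / r.length,
        }
        if per_strand:
            row["density_plus"] = plus / r.length
            row["density_minus"] = minus / r.length
        rows.append(row)
    return pd.DataFrame(rows)


def density_table(
    tracks: dict[str, SignalTrack], enhancers: list[Region]
) -> pd.DataFrame:
    """Enhancer x library density table (rows indexed by enhancer id,
    'class' column plus one density column per library)."""
    out = None
    for lib, track in tracks.items():
        df = enhancer_density(track, enhancers).set_index("enhancer_id")
        if out is None:
            out = df.rename(columns={"density": lib})
        else:
            out[lib] = df["density"]
    return out


def library_correlation(
    table: pd.DataFrame, subset: str | None = None
) -> pd.DataFrame:
    """Pearson correlation between library density columns.

    ``subset`` restricts to one enhancer class.  Zero-variance columns get
    NaN correlations (warned); the diagonal is 1 for valid columns.
    """
    df = table
    if subset is not None:
        df = df[df["class"] == subset]
    libs = [c for c in df.columns if c != "class"]
    if len(df) < 3:
        raise ValueError("need at least 3 enhancers for a correlation matrix")
    X = df[libs].to_numpy(dtype=float)
    for j, lib in enumerate(libs):
        if np.var(X[:, j]) == 0.0:
            warnings.warn(f"library {lib!r} has zero variance over this enhancer set")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(corr, index=libs, columns=libs)


def class_comparison(
    table: pd.DataFrame, library: str, exact_max_n: int = 25
) -> dict:
    """Two-sided Wilcoxon rank-sum test of distal vs super densities.

    Uses the exact null distribution when both groups are small and tie-free,
    otherwise the normal approximation with tie correction.
    """
    distal = table.loc[table["class"] == "distal", library].to_numpy(dtype=float)
    super_ = table.loc[table["class"] == "super", library].to_numpy(dtype=float)
    if distal.size == 0 or super_.size == 0:
        raise ValueError("both enhancer classes must be non-empty")
    pooled = np.concatenate([distal, super_])
    if np.unique(pooled).size == 1:  # degenerate: identical constant groups
        return {
            "library": library,
            "n_distal": int(distal.size),
            "n_super": int(super_.size),
            "U": float(distal.size * super_.size / 2),
            "p_value": 1.0,
            "method": "degenerate",
            "median_distal": float(np.median(distal)),
            "median_super": float(np.median(super_)),
        }
    no_ties = np.unique(pooled).size == pooled.size
    method = (
        "exact"
        if no_ties and max(distal.size, super_.size) <= exact_max_n
        else "asymptotic"
    )
    res = stats.mannwhitneyu(distal, super_, alternative="two-sided", method=method)
    return {
        "library": library,
        "n_distal": int(distal.size),
        "n_super": int(super_.size),
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "median_distal": float(np.median(distal)),
        "median_super": float(np.median(super_)),
    }
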