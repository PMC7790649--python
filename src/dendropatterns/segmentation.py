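"""Equal-count segmentation of ring-width series and per-tree growth attributes.

A tree series of L rings is divided into ``n_segments`` contiguous segments
whose ring counts differ by at most one, so trees of different ages become
comparable 20-variable shape profiles.  Segment boundaries follow the
cumulative-quota rule: segment i (1-based) covers ring indices
``floor((i-1)*L/n) .. floor(i*L/n) - 1``, which spreads the longer segments
evenly along the series.

The standardized profile matrix (per-segment mean widths, each segment
centred and scaled to unit variance across trees) is the input to pattern
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ringio import RingSeries

__all__ = [
    "SegmentProfile",
    "GrowthAttributes",
    "SegmentMatrix",
    "segment_series",
    "standardize_segment_matrix",
    "growth_attributes",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class SegmentProfile:
    """Per-segment mean ring widths for one tree."""

    tree_id: str
    segment_means: np.ndarray  # mm, length n_segments
    segment_counts: np.ndarray  # rings per segment
    segment_year_spans: tuple[tuple[int, int], ...]  # (first_year, last_year) each

    @property
    def n_segments(self) -> int:
        return self.segment_means.size


@dataclass(frozen=True)
class GrowthAttributes:
    """Whole-series growth attributes for one tree."""

    tree_id: str
    age: int  # ring count, years
    mean_rw: float  # mm
    sd_rw: float  # mm, sample SD (n-1)
    p5_rw: float  # mm, 5th percentile (linear interpolation)
    p95_rw: float  # mm, 95th percentile


@dataclass(frozen=True)
class SegmentMatrix:
    """Standardized trees x segments matrix with its scaling parameters."""

    tree_ids: tuple[str, ...]
    values: np.ndarray  # standardized, column mean 0 / sd 1
    col_means: np.ndarray  # mm, per segment
    col_sds: np.ndarray  # mm, per segment (sample SD)

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    def raw(self) -> np.ndarray:
        """Inverse transform: profiles on the original mm scale."""
        return self.values * self.col_sds + self.col_means

    def destandardize_centers(self, centers: np.ndarray) -> np.ndarray:
        """Map cluster centers from standardized back to mm scale."""
        return centers * self.col_sds + self.col_means


def segment_series(series: RingSeries, n_segments: int = 20) -> SegmentProfile:
    """Split a ring series into ``n_segments`` near-equal-count segments.

    The first segment starts at the first ring, the last ends at the last
    ring, and ring counts per segment differ by at most one.
    """
    L = len(series)
    if L < n_segments:
        raise ValueError(
            f"{series.tree_id}: series too short to segment "
            f"({L} rings < {n_segments} segments)"
        )
    bounds = (np.arange(n_segments + 1) * L) // n_segments
    means = np.empty(n_segments)
    counts = np.empty(n_segments, dtype=int)
    spans = []
    for i in range(n_segments):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        means[i] = series.widths[lo:hi].mean()
        counts[i] = hi - lo
        spans.append((series.first_year + lo, series.first_year + hi - 1))
    return SegmentProfile(
        tree_id=series.tree_id,
        segment_means=means,
        segment_counts=counts,
        segment_year_spans=tuple(spans),
    )


def standardize_segment_matrix(profiles: list[SegmentProfile]) -> SegmentMatrix:
    """Stack profiles and centre/scale each segment column to mean 0, sd 1."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to standardize")
    n_seg = profiles[0].n_segments
    if any(p.n_segments != n_seg for p in profiles):
        raise ValueError("profiles have differing segment counts")
    X = np.vstack([p.segment_means for p in profiles])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-variance segment column(s): {list(zero + 1)}")
    return SegmentMatrix(
        tree_ids=tuple(p.tree_id for p in profiles),
        values=(X - means) / sds,
        col_means=means,
        col_sds=sds,
    )


def growth_attributes(series: RingSeries) -> GrowthAttributes:
    """Age, mean/SD ring width and 5th/95th percentile widths of one tree."""
    w = series.widths
    if w.size < 2:
        raise ValueError(f"{series.tree_id}: need >= 2 rings (SD undefined)")
    p5, p95 = np.percentile(w, [5, 95])  # linear interpolation
    return GrowthAttributes(
        tree_id=series.tree_id,
        age=int(w.size),
        mean_rw=float(w.mean()),
        sd_rw=float(w.std(ddof=1)),
        p5_rw=float(p5),
        p95_rw=float(p95),
    )


def profiles_to_frame(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Long-form table of profiles for CSV export."""
    rows = []
    for p in profiles:
        for i in range(p.n_segments):
            y0, y1 = p.segment_year_spans[i]
            rows.append(
                {
                    "tree_id": p.tree_id,
                    "segment_index": i + 1,
                    "mean_mm": float(p.segment_means[i]),
                    "n_rings": int(p.segment_counts[i]),
                    "first_year": y0,
                    "last_year": y1,
                }
            )
    return pd.DataFrame(rows)
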