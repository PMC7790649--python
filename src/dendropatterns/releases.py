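"""Growth-release and suppression detection from ring-width series.

The percent growth change for year t compares the mean ring width of the
10-year window ending at t (M1) with the mean of the following 10-year
window (M2):

    %GC = (M2 - M1) / M1 * 100

Years are classified by the printed thresholds: major release %GC >= 50,
minor release 25 <= %GC < 50, minor suppression -50 < %GC <= -25, major
suppression %GC <= -50, otherwise no event.  Edge years lacking two complete
windows are undefined.  Site chronologies express, per calendar year, the
percentage of sampled trees in each class; smoothed with a tricube-weighted
local polynomial regression (loess).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, find_peaks

from .clustering import PatternPartition
from .ringio import RingSeries
from .segmentation import SegmentProfile

__all__ = [
    "ReleaseThresholds",
    "GrowthChangeSeries",
    "SiteChronology",
    "ReleasePeak",
    "CLASSES",
    "percent_growth_change",
    "classify_growth_change",
    "site_change_chronology",
    "loess_smooth",
    "detect_release_peaks",
    "pattern_section_frequencies",
]

CLASSES = (
    "major_release",
    "minor_release",
    "none",
    "minor_suppression",
    "major_suppression",
)
EVENT_CLASSES = tuple(c for c in CLASSES if c != "none")


@dataclass(frozen=True)
class ReleaseThresholds:
    major: float = 50.0  # percent
    minor: float = 25.0  # percent
    window: int = 10  # years

    def __post_init__(self) -> None:
        if not self.major > self.minor > 0:
            raise ValueError("need major > minor > 0")
        if self.window < 2:
            raise ValueError("window must be >= 2 years")


@dataclass(frozen=True)
class GrowthChangeSeries:
    """Per-year %GC values and classes for one tree.

    Only years with two complete windows are present; a year whose first
    window mean is zero has gc = NaN and class 'undefined'.
    """

    tree_id: str
    years: np.ndarray
    gc: np.ndarray  # percent
    classes: np.ndarray  # dtype object / str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "year": self.years,
                "gc": self.gc,
                "class": self.classes,
            }
        )


def percent_growth_change(
    series: RingSeries, thresholds: ReleaseThresholds = ReleaseThresholds()
) -> GrowthChangeSeries:
    """Two-window percent growth change along one tree series."""
    w = thresholds.window
    x = series.widths
    if x.size < 2 * w:
        raise ValueError(
            f"{series.tree_id}: series shorter than two windows "
            f"({x.size} < {2 * w})"
        )
    csum = np.concatenate([[0.0], np.cumsum(x)])
    # t indexes the last year of the first window: t in [w-1, L-w-1]
    t = np.arange(w - 1, x.size - w)
    m1 = (csum[t + 1] - csum[t + 1 - w]) / w
    m2 = (csum[t + 1 + w] - csum[t + 1]) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(m1 > 0, (m2 - m1) / m1 * 100.0, np.nan)
    classes = np.array([classify_growth_change(v, thresholds) for v in gc], dtype=object)
    return GrowthChangeSeries(
        tree_id=series.tree_id,
        years=series.first_year + t,
        gc=gc,
        classes=classes,
    )


def classify_growth_change(
    gc: float, thresholds: ReleaseThresholds = ReleaseThresholds()
) -> str:
    """Map one %GC value to its event class (boundaries inclusive as printed)."""
    if not np.isfinite(gc):
        return "undefined"
    if gc >= thresholds.major:
        return "major_release"
    if gc >= thresholds.minor:
        return "minor_release"
    if gc <= -thresholds.major:
        return "major_suppression"
    if gc <= -thresholds.minor:
        return "minor_suppression"
    return "none"


@dataclass
class SiteChronology:
    """Per-year percentages of trees in each growth-change class at one site."""

    site_id: str
    table: pd.DataFrame  # year, n_trees, pct_<class>, pct_all_releases, ...
    span: float = 0.5  # loess span used for the smoothed columns
    smoothed: pd.DataFrame = field(default_factory=pd.DataFrame)


def site_change_chronology(
    trees: list[GrowthChangeSeries],
    site_id: str = "",
    span: float = 0.5,
    degree: int = 2,
) -> SiteChronology:
    """Annual class percentages over all trees with a defined %GC that year.

    Adds combined 'all_releases' (minor + major) and 'all_suppressions'
    columns; years with zero eligible trees are omitted.  Each percentage
    column is loess-smoothed with the given span.
    """
    if not trees:
        raise ValueError("need at least one tree")
    frames = [t.to_frame() for t in trees]
    df = pd.concat(frames, ignore_index=True)
    df = df[df["class"] != "undefined"]
    if df.empty:
        raise ValueError("no defined %GC values at this site")
    rows = []
    for year, grp in df.groupby("year"):
        n = len(grp)
        row = {"year": int(year), "n_trees": n}
        for cls in EVENT_CLASSES:
            row[f"pct_{cls}"] = 100.0 * (grp["class"] == cls).sum() / n
        row["pct_all_releases"] = row["pct_major_release"] + row["pct_minor_release"]
        row["pct_all_suppressions"] = (
            row["pct_major_suppression"] + row["pct_minor_suppression"]
        )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    smoothed = pd.DataFrame({"year": table["year"]})
    x = table["year"].to_numpy(dtype=float)
    for col in table.columns:
        if col.startswith("pct_"):
            y = table[col].to_numpy()
            # chronologies shorter than a local fit are passed through unsmoothed
            smoothed[col] = (
                loess_smooth(x, y, span=span, degree=degree) if x.size >= degree + 2 else y
            )
    return SiteChronology(site_id=site_id, table=table, span=span, smoothed=smoothed)


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.5, degree: int = 2
) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at each x.

    For each point the span-nearest neighbours are fit by weighted least
    squares with tricube weights on distance; the fitted polynomial is
    evaluated at the point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    q = max(degree + 2, int(np.ceil(span * n)))
    q = min(q, n)
    out = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, xi in enumerate(x):
        d = np.abs(xs - xi)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = (1 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
        keep = w > 0
        xw, yw, ww = xs[idx][keep], ys[idx][keep], w[keep]
        # centred design for numerical stability
        X = np.vander(xw - xi, degree + 1, increasing=True)
        sw = np.sqrt(ww)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        out[i] = beta[0]
    return out


@dataclass(frozen=True)
class ReleasePeak:
    """One detected release episode: the peak year and its bounding interval."""

    year: int
    start_year: int  # nearest flanking minimum (or series start)
    end_year: int  # nearest flanking minimum (or series end)
    height: float  # percent of trees in release at the smoothed peak


def detect_release_peaks(
    chronology: SiteChronology,
    min_height: float = 5.0,
    min_separation: int = 15,
    span: float = 0.15,
    degree: int = 2,
) -> list[ReleasePeak]:
    """Locate release episodes on the combined-release curve.

    The raw all-release percentages are re-smoothed at a detection ``span``
    finer than the display smoothing, then local maxima at least
    ``min_height`` percent high and ``min_separation`` years apart are
    reported, each bounded by its nearest flanking minima.
    """
    tab = chronology.table
    years = tab["year"].to_numpy(dtype=float)
    y = loess_smooth(years, tab["pct_all_releases"].to_numpy(), span=span, degree=degree)
    # median year step (chronology years are usually consecutive)
    step = float(np.median(np.diff(years))) if years.size > 1 else 1.0
    distance = max(1, int(round(min_separation / step)))
    peaks, _ = find_peaks(y, height=min_height, distance=distance)
    minima = argrelextrema(y, np.less_equal, order=1)[0]
    out = []
    for p in peaks:
        left = minima[minima < p]
        right = minima[minima > p]
        i0 = int(left.max()) if left.size else 0
        i1 = int(right.min()) if right.size else y.size - 1
        out.append(
            ReleasePeak(
                year=int(years[p]),
                start_year=int(years[i0]),
                end_year=int(years[i1]),
                height=float(y[p]),
            )
        )
    return out


def pattern_section_frequencies(
    gc_series: list[GrowthChangeSeries],
    profiles: list[SegmentProfile],
    partition: PatternPartition,
) -> pd.DataFrame:
    """Percent of trees of each pattern with each event class in each section.

    A tree counts for (pattern, section, class) if any year within that
    section's calendar span carries that class; percentages are relative to
    the number of trees of the pattern.
    """
    patterns = partition.pattern_of()
    prof_by_id = {p.tree_id: p for p in profiles}
    gc_ids = [g.tree_id for g in gc_series]
    missing = [t for t in gc_ids if t not in patterns] + [
        t for t in gc_ids if t not in prof_by_id
    ]
    if missing:
        raise ValueError(f"trees missing from partition or profiles: {sorted(set(missing))}")
    n_seg = profiles[0].n_segments
    pattern_names = sorted(set(patterns[t] for t in gc_ids))
    totals = {p: 0 for p in pattern_names}
    counts: dict[tuple[str, int, str], int] = {}
    for g in gc_series:
        pat = patterns[g.tree_id]
        totals[pat] += 1
        prof = prof_by_id[g.tree_id]
        for sec in range(n_seg):
            y0, y1 = prof.segment_year_spans[sec]
            in_span = (g.years >= y0) & (g.years <= y1)
            present = set(g.classes[in_span]) & set(EVENT_CLASSES)
            for cls in present:
                key = (pat, sec + 1, cls)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    for pat in pattern_names:
        for sec in range(1, n_seg + 1):
            row = {"pattern": pat, "section": sec}
            for cls in EVENT_CLASSES:
                c = counts.get((pat, sec, cls), 0)
                row[f"pct_{cls}"] = 100.0 * c / totals[pat]
            rows.append(row)
    return pd.DataFrame(rows)
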