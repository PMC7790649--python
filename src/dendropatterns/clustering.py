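"""Radial growth-pattern identification.

Trees' standardized 20-segment profiles are partitioned by k-means run as a
large number of random restarts of Lloyd's algorithm, keeping the restart
with the smallest within-cluster sum of squares.  The number of patterns k
is chosen by maximizing the simple structure index (SSI), a cluster-validity
score that rewards partitions whose centers differ strongly on individual
segment variables, realized by well-populated clusters, while deviating from
the grand mean.

For a partition with centers :math:`c_{kj}` (k clusters, p variables) and
cluster sizes :math:`n_k`, with, per variable j, ``span_j`` the max-min
center difference, ``hi_j``/``lo_j`` the clusters attaining that max/min and
``d_j`` the absolute deviation of the variable's center mean from the grand
center mean, the index used here is

    SSI = sum_j span_j * exp(-d_j) * sqrt(n_hi_j * n_lo_j)
          / (p * max_k(n_k over attaining clusters) * exp(-min_j d_j))

the size-weighted variant of the index as implemented in the standard
community-ecology toolchain.  It is invariant to cluster relabelling and to
duplicating every observation.

Clusters are then named by deterministic rules on their de-standardized
centers: a flat narrow center is *linear*; a last-third maximum is
*ascending*; an interior maximum with a declining tail is *sine* when the
first third is narrow (juvenile suppression) and *bell* when growth is high
from the start.  Within a shape group, clusters are ranked low/moderate/high
by mean center width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .segmentation import SegmentMatrix

__all__ = [
    "PatternPartition",
    "LabelThresholds",
    "SelectKResult",
    "best_kmeans",
    "ssi_score",
    "select_pattern_count",
    "name_patterns",
]

SHAPES = ("linear", "bell", "ascending", "sine")


@dataclass(frozen=True)
class LabelThresholds:
    """Tunable thresholds for the shape-naming rules.

    linear_range_frac: a center whose max-min range is below this fraction of
        its mean width is called linear (flat profile).
    decline_frac: minimum relative drop of the last-third mean below the
        center maximum for a declining tail (bell/sine).
    narrow_start_frac: first-third mean below this fraction of the center
        maximum marks juvenile suppression (sine rather than bell); suppressed
        starts sit well below two-thirds of the peak, gap-origin starts near it.
    """

    linear_range_frac: float = 0.25
    decline_frac: float = 0.25
    narrow_start_frac: float = 0.65


@dataclass(frozen=True)
class PatternPartition:
    """A k-means partition of segment profiles into growth patterns."""

    k: int
    tree_ids: tuple[str, ...]
    assignments: np.ndarray  # cluster index per tree, 0-based
    centers: np.ndarray  # k x p, standardized scale
    within_ss: float
    ssi: float | None = None
    labels: dict[int, tuple[str, str]] | None = None  # cluster -> (shape, level)
    label_flags: dict[int, bool] | None = None  # cluster -> ambiguous-rule flag

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.shape != (len(self.tree_ids),):
            raise ValueError("one assignment per tree required")
        sizes = np.bincount(a, minlength=self.k)
        if np.any(sizes == 0):
            raise ValueError("empty cluster in partition")
        if self.within_ss < 0:
            raise ValueError("within_ss must be nonnegative")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def assignment_of(self) -> dict[str, int]:
        return dict(zip(self.tree_ids, (int(c) for c in self.assignments)))

    def label_name(self, cluster: int) -> str:
        """Human-readable pattern name, e.g. 'high_sine' or 'linear'."""
        if self.labels is None:
            return f"cluster_{cluster}"
        shape, level = self.labels[cluster]
        return shape if level == "none" else f"{level}_{shape}"

    def pattern_of(self) -> dict[str, str]:
        """tree_id -> pattern name."""
        return {
            tid: self.label_name(int(c))
            for tid, c in zip(self.tree_ids, self.assignments)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, c in zip(self.tree_ids, self.assignments):
            shape, level = (
                self.labels[int(c)] if self.labels is not None else ("", "")
            )
            rows.append(
                {
                    "tree_id": tid,
                    "cluster": int(c),
                    "shape": shape,
                    "level": level,
                    "pattern": self.label_name(int(c)),
                }
            )
        return pd.DataFrame(rows)


def best_kmeans(
    matrix: SegmentMatrix, k: int, n_restarts: int = 1000, seed: int | None = None
) -> PatternPartition:
    """Best-of-``n_restarts`` Lloyd k-means on the standardized profiles.

    Each restart draws random initial centers; the partition with minimal
    within-cluster sum of squares is returned.  Deterministic given ``seed``.
    """
    n = matrix.n_trees
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, n_trees={n}]")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point warnings at k == n
        km.fit(matrix.values)
    part = PatternPartition(
        k=k,
        tree_ids=matrix.tree_ids,
        assignments=km.labels_.astype(int),
        centers=km.cluster_centers_,
        within_ss=float(km.inertia_),
    )
    return replace(part, ssi=ssi_score(matrix, part))


def ssi_score(matrix: SegmentMatrix, partition: PatternPartition) -> float:
    """Simple structure index of a partition (higher = cleaner structure)."""
    if partition.k < 2:
        raise ValueError("SSI undefined for k < 2")
    centers = np.asarray(partition.centers, dtype=float)
    sizes = partition.sizes.astype(float)
    p = centers.shape[1]
    order = np.argsort(centers, axis=0, kind="stable")
    hi = order[-1, :]  # cluster attaining the max center per variable
    lo = order[0, :]  # cluster attaining the min
    span = centers.max(axis=0) - centers.min(axis=0)
    grand = centers.mean()
    dev = np.abs(centers.mean(axis=0) - grand)
    n_hi = sizes[hi]
    n_lo = sizes[lo]
    norm = p * max(n_hi.max(), n_lo.max()) * np.exp(-dev.min())
    return float((span * np.exp(-dev)) @ np.sqrt(n_hi * n_lo) / norm)


@dataclass(frozen=True)
class SelectKResult:
    """SSI curve over candidate k with the winning partition."""

    k_best: int
    curve: pd.DataFrame  # columns: k, ssi, within_ss
    partitions: dict[int, PatternPartition]
    low_confidence: bool

    @property
    def best(self) -> PatternPartition:
        return self.partitions[self.k_best]


def select_pattern_count(
    matrix: SegmentMatrix,
    k_range: range | list[int],
    n_restarts: int = 1000,
    seed: int | None = None,
    null_margin: float = 1.4,
) -> SelectKResult:
    """Choose the number of growth patterns by maximizing SSI over ``k_range``.

    Ties break toward smaller k (parsimony).  The selection is flagged low
    confidence when the best observed SSI does not exceed ``null_margin``
    times the best SSI of a structure-free reference built by independently
    permuting each segment column (which preserves marginals but destroys
    any joint cluster structure): on such data any k looks as good as any
    other and the argmax is not meaningful.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = matrix.n_trees
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * len(ks) + 1) % (2**31)
    partitions = {}
    rows = []
    for k, s in zip(ks, child_seeds[: len(ks)]):
        part = best_kmeans(matrix, k, n_restarts=n_restarts, seed=int(s))
        partitions[k] = part
        rows.append({"k": k, "ssi": part.ssi, "within_ss": part.within_ss})
    curve = pd.DataFrame(rows)
    ssi = curve["ssi"].to_numpy()
    k_best = int(curve["k"].iloc[int(np.argmax(ssi))])  # argmax takes first max

    # structure-free reference: permute each column independently
    rng = np.random.default_rng(child_seeds[len(ks)])
    null_values = np.column_stack(
        [rng.permutation(matrix.values[:, j]) for j in range(matrix.n_segments)]
    )
    null_matrix = SegmentMatrix(
        tree_ids=matrix.tree_ids,
        values=null_values,
        col_means=matrix.col_means,
        col_sds=matrix.col_sds,
    )
    null_best = max(
        best_kmeans(null_matrix, k, n_restarts=n_restarts, seed=int(s)).ssi
        for k, s in zip(ks, child_seeds[len(ks) + 1 :])
    )
    return SelectKResult(
        k_best=k_best,
        curve=curve,
        partitions=partitions,
        low_confidence=bool(ssi.max() <= null_margin * null_best),
    )


def _shape_features(center: np.ndarray) -> dict[str, float]:
    c = np.asarray(center, dtype=float)
    n = c.size
    t1 = c[: n // 3].mean()
    t2 = c[n // 3 : 2 * n // 3].mean()
    t3 = c[2 * n // 3 :].mean()
    h1 = c[: n // 2].mean()
    h2 = c[n // 2 :].mean()
    peak = int(np.argmax(c))
    return {
        "mean": c.mean(),
        "range": c.max() - c.min(),
        "max": c.max(),
        "t1": t1,
        "t2": t2,
        "t3": t3,
        "h1": h1,
        "h2": h2,
        "peak_frac": peak / (n - 1),
    }


def _classify_shape(
    center: np.ndarray, th: LabelThresholds
) -> tuple[str, bool]:
    """Shape of one de-standardized center; flag True if rules were ambiguous."""
    f = _shape_features(center)
    if f["range"] < th.linear_range_frac * f["mean"]:
        return "linear", False
    tail_decline = (f["max"] - f["t3"]) / f["max"] if f["max"] > 0 else 0.0
    narrow_start = f["t1"] < th.narrow_start_frac * f["max"]
    asc = f["t3"] >= max(f["t1"], f["t2"]) and f["h1"] < f["h2"]
    bell = (
        f["peak_frac"] < 0.5
        and tail_decline >= th.decline_frac
        and not narrow_start
    )
    sine = (
        0.2 <= f["peak_frac"] <= 0.9
        and tail_decline >= th.decline_frac
        and narrow_start
    )
    matches = [s for s, hit in (("ascending", asc), ("bell", bell), ("sine", sine)) if hit]
    if len(matches) == 1:
        return matches[0], False
    # ambiguous: deterministic precedence chain, flagged
    if f["t3"] >= max(f["t1"], f["t2"]):
        return "ascending", True
    if narrow_start:
        return "sine", True
    return "bell", True


def name_patterns(
    partition: PatternPartition,
    matrix: SegmentMatrix,
    thresholds: LabelThresholds = LabelThresholds(),
) -> PatternPartition:
    """Attach (shape, level) labels to each cluster of a partition.

    Shapes come from the rule set above applied to centers on the raw mm
    scale; levels rank clusters of the same shape by mean center width
    (low/moderate/high; a lone cluster in its shape gets level 'none').
    """
    centers_mm = matrix.destandardize_centers(partition.centers)
    shapes = {}
    flags = {}
    for c in range(partition.k):
        shapes[c], flags[c] = _classify_shape(centers_mm[c], thresholds)
    labels: dict[int, tuple[str, str]] = {}
    for shape in set(shapes.values()):
        members = [c for c in range(partition.k) if shapes[c] == shape]
        members.sort(key=lambda c: centers_mm[c].mean())
        m = len(members)
        if m == 1:
            levels = ["none"]
        elif m == 2:
            levels = ["low", "high"]
        else:
            levels = ["low"] + ["moderate"] * (m - 2) + ["high"]
        for c, lev in zip(members, levels):
            labels[c] = (shape, lev)
    return replace(partition, labels=labels, label_flags=flags)
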