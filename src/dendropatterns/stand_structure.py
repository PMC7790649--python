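"""Stand-structure metrics: canopy layers, dominant height, summaries, CBAP.

Dominant height (DH) is the mean height of the 100 tallest trees per
hectare — four trees on a 400 m² plot.  Canopy layers follow the provincial
survey rules: dominant trees reach at least DH, codominant at least 2/3 DH,
intermediary more than 1/2 DH, suppressed the rest (a height of exactly
1/2 DH is suppressed, since the intermediary bound is strict).

The cohort basal area proportion (CBAP) measures how far post-disturbance
cohorts have replaced the first cohort: 0 when all living basal area belongs
to the first cohort, 1 when none does.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ringio import PlotInventory

__all__ = [
    "CanopyLayer",
    "StandSummary",
    "dominant_height",
    "assign_canopy_layer",
    "assign_layers",
    "stand_summary",
    "assign_cohorts",
    "compute_cbap",
]


class CanopyLayer(str, enum.Enum):
    DOMINANT = "dominant"
    CODOMINANT = "codominant"
    INTERMEDIARY = "intermediary"
    SUPPRESSED = "suppressed"


def dominant_height(plot: PlotInventory, intact_only: bool = False) -> float:
    """Mean height of the 100-tallest-per-hectare living trees of a plot.

    The number of top trees scales with plot area (four on 400 m²); plots
    with fewer living trees use all of them, with a warning.
    """
    trees = plot.living
    if intact_only:
        trees = trees[trees["crown_status"] == "intact"]
    heights = trees["height_m"].to_numpy(dtype=float)
    heights = heights[np.isfinite(heights)]
    if heights.size == 0:
        raise ValueError(f"plot {plot.plot_id}: no measured heights")
    n_top = max(1, round(100 * plot.area_ha))
    if heights.size < n_top:
        warnings.warn(
            f"plot {plot.plot_id}: only {heights.size} trees for a "
            f"{n_top}-tree dominant height"
        )
        n_top = heights.size
    top = np.sort(heights)[-n_top:]
    return float(top.mean())


def assign_canopy_layer(height: float, dh: float) -> CanopyLayer:
    """Canopy layer of one tree from its height and the plot dominant height."""
    if height <= 0 or dh <= 0:
        raise ValueError("height and DH must be positive")
    if height >= dh:
        return CanopyLayer.DOMINANT
    if height >= 2 / 3 * dh:
        return CanopyLayer.CODOMINANT
    if height > 0.5 * dh:
        return CanopyLayer.INTERMEDIARY
    return CanopyLayer.SUPPRESSED


def assign_layers(plot: PlotInventory, dh: float | None = None) -> pd.DataFrame:
    """Living trees of a plot with a ``canopy_layer`` column added."""
    if dh is None:
        dh = dominant_height(plot)
    living = plot.living.copy()
    living["canopy_layer"] = [
        assign_canopy_layer(h, dh).value for h in living["height_m"]
    ]
    return living


@dataclass(frozen=True)
class StandSummary:
    """Structural attributes of one stand (per-hectare scale)."""

    plot_id: str
    tree_density: float  # living stems / ha
    sapling_density: float  # / ha
    snag_density: float  # / ha
    tree_basal_area: float  # m2 / ha, living
    snag_basal_area: float  # m2 / ha
    composition_pct: dict[str, float]  # species -> % of living basal area
    max_height: float  # m
    dominant_height: float  # m
    mean_height: float  # m
    sd_height: float  # m
    oldest_age: float | None  # years, from ring data when given
    mean_age: float | None
    sd_age: float | None
    cbap: float | None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "plot_id": self.plot_id,
            "tree_density_n_ha": self.tree_density,
            "sapling_density_n_ha": self.sapling_density,
            "snag_density_n_ha": self.snag_density,
            "tree_basal_area_m2_ha": self.tree_basal_area,
            "snag_basal_area_m2_ha": self.snag_basal_area,
            "max_height_m": self.max_height,
            "dominant_height_m": self.dominant_height,
            "mean_height_m": self.mean_height,
            "sd_height_m": self.sd_height,
            "oldest_age_years": self.oldest_age,
            "mean_age_years": self.mean_age,
            "sd_age_years": self.sd_age,
            "cbap": self.cbap,
        }
        for sp, pct in sorted(self.composition_pct.items()):
            d[f"pct_basal_area_{sp}"] = pct
        return pd.DataFrame([d])


def _basal_area_m2(dbh_cm: np.ndarray) -> np.ndarray:
    return math.pi * (dbh_cm / 200.0) ** 2  # DBH cm -> radius m


def stand_summary(
    plot: PlotInventory,
    ages: Mapping[str, int] | None = None,
    cohorts: Mapping[str, int] | None = None,
) -> StandSummary:
    """Per-hectare densities, basal areas, composition and height/age stats.

    ``ages`` (tree_id -> ring count) enables the age statistics; ``cohorts``
    (tree_id -> cohort index, 1 = first cohort) additionally enables CBAP.
    Trees without a DBH are excluded from basal areas with a warning.
    """
    living = plot.living
    snags = plot.snags
    area = plot.area_ha

    def ba_sum(df: pd.DataFrame) -> float:
        dbh = df["dbh_cm"].to_numpy(dtype=float)
        ok = np.isfinite(dbh)
        if (~ok).any():
            warnings.warn(
                f"plot {plot.plot_id}: {(~ok).sum()} tree(s) without DBH "
                "excluded from basal area"
            )
        return float(_basal_area_m2(dbh[ok]).sum())

    living_ba = ba_sum(living)
    comp = {}
    if living_ba > 0:
        for sp, grp in living.groupby("species"):
            comp[str(sp)] = 100.0 * ba_sum(grp) / living_ba
    heights = living["height_m"].to_numpy(dtype=float)
    heights = heights[np.isfinite(heights)]
    age_vals = None
    if ages is not None:
        age_vals = np.array(
            [ages[t] for t in living["tree_id"] if t in ages], dtype=float
        )
        if age_vals.size == 0:
            age_vals = None
    cbap = None
    if cohorts is not None and ages is not None:
        cbap = compute_cbap(plot, cohorts)
    sap_density = (
        plot.sapling_count / (plot.sapling_area_m2 / 10_000.0)
        if plot.sapling_area_m2 > 0
        else 0.0
    )
    return StandSummary(
        plot_id=plot.plot_id,
        tree_density=len(living) / area,
        sapling_density=sap_density,
        snag_density=len(snags) / area,
        tree_basal_area=living_ba / area,
        snag_basal_area=ba_sum(snags) / area if len(snags) else 0.0,
        composition_pct=comp,
        max_height=float(heights.max()) if heights.size else float("nan"),
        dominant_height=dominant_height(plot),
        mean_height=float(heights.mean()) if heights.size else float("nan"),
        sd_height=float(heights.std(ddof=1)) if heights.size > 1 else float("nan"),
        oldest_age=float(age_vals.max()) if age_vals is not None else None,
        mean_age=float(age_vals.mean()) if age_vals is not None else None,
        sd_age=float(age_vals.std(ddof=1)) if age_vals is not None else None,
        cbap=cbap,
    )


def assign_cohorts(
    ages: Mapping[str, int], breaks: Sequence[float]
) -> dict[str, int]:
    """Assign each tree to an establishment cohort from age cutoffs.

    ``breaks`` are age thresholds in years (any order).  Cohort 1 holds the
    trees at least as old as the largest break — those established before or
    at the last primary disturbance; each successive break opens the next
    younger cohort.  With m breaks there are m+1 cohorts.
    """
    if not breaks:
        warnings.warn("no cohort breaks given; all trees in cohort 1")
        return {t: 1 for t in ages}
    cuts = sorted(set(float(b) for b in breaks), reverse=True)
    if len(cuts) != len(breaks):
        raise ValueError("cohort breaks must be distinct")
    out = {}
    for tid, age in ages.items():
        cohort = len(cuts) + 1  # youngest cohort by default
        for i, cut in enumerate(cuts, start=1):
            if age >= cut:
                cohort = i
                break
        out[tid] = cohort
    return out


def compute_cbap(plot: PlotInventory, cohorts: Mapping[str, int]) -> float:
    """Cohort basal area proportion: 1 - BA(first cohort) / BA(all living).

    Exactly 0 when every living tree belongs to cohort 1, exactly 1 when no
    first-cohort basal area remains.
    """
    living = plot.living
    missing = [t for t in living["tree_id"] if t not in cohorts]
    if missing:
        raise ValueError(f"living trees without a cohort: {missing}")
    dbh = living["dbh_cm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dbh)):
        raise ValueError("living trees must all have a DBH for CBAP")
    ba = _basal_area_m2(dbh)
    total = ba.sum()
    if total == 0:
        raise ValueError("zero total basal area")
    first = np.array([cohorts[t] == 1 for t in living["tree_id"]])
    return float(1.0 - ba[first].sum() / total)
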