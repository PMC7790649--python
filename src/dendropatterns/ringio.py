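"""Ring-width and inventory I/O.

Reads and writes tree-ring series in the Tucson ("rwl") decadal format and in
a long-form CSV, merges the two measured radii of a stem disk into a single
tree series, and loads plot inventory / sapling tally tables.

Tucson dialects are distinguished by the end-of-series marker: ``999`` means
values are hundredths of a millimetre, ``-9999`` thousandths.  All widths are
held internally in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "RadiusSeries",
    "PlotInventory",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_rings_csv",
    "write_rings_csv",
    "combine_radii",
    "read_inventory_csv",
    "read_saplings_csv",
]

#: columns required in a plot inventory CSV
INVENTORY_COLUMNS = (
    "tree_id",
    "species",
    "dbh_cm",
    "height_m",
    "vitality",
    "crown_status",
    "plot_id",
    "plot_area_m2",
)

MERCHANTABLE_DBH_CM = 9.0


class RwlParseError(ValueError):
    """Raised when a Tucson file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class RingSeries:
    """A dated annual ring-width series for one tree (mm/year).

    Years are consecutive: ring ``widths[i]`` formed in ``first_year + i``.
    A width of 0 encodes a locally absent ring.
    """

    tree_id: str
    first_year: int
    widths: np.ndarray
    site_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError(f"{self.tree_id}: widths must be a non-empty 1-D array")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"{self.tree_id}: widths contain non-finite values")
        if np.any(w < 0):
            raise ValueError(f"{self.tree_id}: negative ring width")
        object.__setattr__(self, "widths", w)

    def __len__(self) -> int:
        return self.widths.size

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


@dataclass(frozen=True)
class RadiusSeries(RingSeries):
    """One measured radius of a stem disk (two radii make a tree series)."""

    radius_id: str = ""


@dataclass
class PlotInventory:
    """Trees and saplings surveyed on one fixed-area plot.

    ``trees`` holds one row per merchantable stem (DBH >= 9 cm) with columns
    ``tree_id, species, dbh_cm, height_m, vitality, crown_status`` and an
    optional ``canopy_layer``.
    """

    plot_id: str
    plot_area_m2: float
    trees: pd.DataFrame
    sapling_count: int = 0
    sapling_area_m2: float = 0.0

    def __post_init__(self) -> None:
        if self.plot_area_m2 <= 0:
            raise ValueError("plot_area_m2 must be positive")
        t = self.trees.reset_index(drop=True).copy()
        needed = {"tree_id", "species", "dbh_cm", "height_m", "vitality", "crown_status"}
        missing = needed - set(t.columns)
        if missing:
            raise ValueError(f"inventory missing columns: {sorted(missing)}")
        dbh = t["dbh_cm"].to_numpy(dtype=float)
        bad = t.loc[np.isfinite(dbh) & (dbh < MERCHANTABLE_DBH_CM), "tree_id"]
        if len(bad):
            raise ValueError(
                "trees below the merchantable threshold "
                f"(DBH < {MERCHANTABLE_DBH_CM} cm): {list(bad)}"
            )
        if t["tree_id"].duplicated().any():
            raise ValueError("duplicate tree_id in inventory")
        self.trees = t

    @property
    def area_ha(self) -> float:
        return self.plot_area_m2 / 10_000.0

    @property
    def living(self) -> pd.DataFrame:
        return self.trees[self.trees["vitality"] == "alive"]

    @property
    def snags(self) -> pd.DataFrame:
        return self.trees[self.trees["vitality"] == "dead"]


# ---------------------------------------------------------------------------
# Tucson / rwl
# ---------------------------------------------------------------------------

_END_MARKERS = {999: 100.0, -9999: 1000.0}  # marker -> divisor to mm


def read_rwl(path: str | Path) -> list[RingSeries]:
    """Read a Tucson decadal ring-width file.

    Returns one :class:`RingSeries` per series id, widths in mm.  The unit
    (0.01 vs 0.001 mm) is inferred per series from its end marker.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    closed: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise RwlParseError(f"{path}:{lineno}: malformed decade line")
            sid = parts[0]
            try:
                decade = int(parts[1])
                values = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise RwlParseError(f"{path}:{lineno}: malformed decade line") from exc
            if sid in closed:
                raise RwlParseError(f"{path}:{lineno}: duplicate series id {sid!r}")
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((decade, values))
            if any(v in _END_MARKERS for v in values):
                closed.add(sid)

    out = []
    for sid in order:
        chunks = sorted(raw[sid])
        first_year = chunks[0][0]
        flat: list[int] = []
        for decade, values in chunks:
            expected = first_year + len(flat)
            if decade != expected:
                raise RwlParseError(
                    f"{path}: series {sid!r}: decade line {decade} does not "
                    f"follow year {expected - 1}"
                )
            flat.extend(values)
        marker = flat[-1]
        if marker not in _END_MARKERS:
            raise RwlParseError(f"{path}: series {sid!r} lacks an end marker")
        divisor = _END_MARKERS[marker]
        widths = np.asarray(flat[:-1], dtype=float) / divisor
        out.append(RingSeries(tree_id=sid, first_year=first_year, widths=widths))
    return out


def write_rwl(
    series: Iterable[RingSeries], path: str | Path, precision: float = 0.01
) -> None:
    """Write series to a Tucson decadal file at 0.01 or 0.001 mm precision."""
    if precision not in (0.01, 0.001):
        raise ValueError("precision must be 0.01 or 0.001 (mm)")
    factor = round(1.0 / precision)
    marker = 999 if precision == 0.01 else -9999
    lines = []
    for s in series:
        if len(s.tree_id) > 8:
            raise ValueError(f"series id {s.tree_id!r} exceeds 8 characters")
        values = [int(round(w * factor)) for w in s.widths] + [marker]
        year = s.first_year
        i = 0
        while i < len(values):
            # each line runs to the end of the current decade
            n = 10 - (year % 10)
            chunk = values[i : i + n]
            cells = "".join(f"{v:6d}" for v in chunk)
            lines.append(f"{s.tree_id:<8}{year:4d}{cells}")
            i += len(chunk)
            year += len(chunk)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-form CSV alternative
# ---------------------------------------------------------------------------


def read_rings_csv(path: str | Path) -> list[RingSeries]:
    """Read ring widths from long-form CSV (tree_id, year, width_mm[, site_id, species])."""
    df = pd.read_csv(path)
    needed = {"tree_id", "year", "width_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("tree_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError(f"{path}: series {tid!r} has non-consecutive years")
        out.append(
            RingSeries(
                tree_id=str(tid),
                first_year=int(years[0]),
                widths=grp["width_mm"].to_numpy(dtype=float),
                site_id=str(grp["site_id"].iloc[0]) if "site_id" in grp else "",
                species=str(grp["species"].iloc[0]) if "species" in grp else "",
            )
        )
    return out


def write_rings_csv(series: Iterable[RingSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for year, width in zip(s.years, s.widths):
            rows.append(
                {
                    "tree_id": s.tree_id,
                    "year": int(year),
                    "width_mm": float(width),
                    "site_id": s.site_id,
                    "species": s.species,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Radius merging
# ---------------------------------------------------------------------------


def combine_radii(a: RingSeries, b: RingSeries) -> RingSeries:
    """Average two dated radii of one tree into a single tree series.

    The output spans the union of the two calendar spans; a year measured in
    only one radius keeps that radius's value, a year measured in both gets
    the mean.  The spans must overlap (disjoint radii cannot belong to one
    dated tree).
    """
    if a.first_year > b.last_year or b.first_year > a.last_year:
        raise ValueError(
            f"radius spans are disjoint: {a.first_year}-{a.last_year} vs "
            f"{b.first_year}-{b.last_year}"
        )
    first = min(a.first_year, b.first_year)
    last = max(a.last_year, b.last_year)
    n = last - first + 1
    total = np.zeros(n)
    count = np.zeros(n)
    for s in (a, b):
        i0 = s.first_year - first
        total[i0 : i0 + len(s)] += s.widths
        count[i0 : i0 + len(s)] += 1
    return RingSeries(
        tree_id=a.tree_id,
        first_year=first,
        widths=total / count,
        site_id=a.site_id or b.site_id,
        species=a.species or b.species,
    )


# ---------------------------------------------------------------------------
# Inventory tables
# ---------------------------------------------------------------------------


def read_inventory_csv(
    path: str | Path, saplings: Mapping[str, tuple[int, float]] | None = None
) -> list[PlotInventory]:
    """Read a plot inventory CSV (one row per tree) into per-plot inventories.

    ``saplings`` optionally maps plot_id -> (sapling_count, sapling_area_m2),
    e.g. as returned by :func:`read_saplings_csv`.
    """
    df = pd.read_csv(path)
    missing = set(INVENTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    plots = []
    for pid, grp in df.groupby("plot_id", sort=False):
        area = float(grp["plot_area_m2"].iloc[0])
        count, sap_area = (saplings or {}).get(str(pid), (0, 0.0))
        plots.append(
            PlotInventory(
                plot_id=str(pid),
                plot_area_m2=area,
                trees=grp.drop(columns=["plot_id", "plot_area_m2"]),
                sapling_count=count,
                sapling_area_m2=sap_area,
            )
        )
    return plots


def read_saplings_csv(path: str | Path) -> dict[str, tuple[int, float]]:
    """Read a sapling tally CSV (plot_id, sapling_count, sapling_area_m2)."""
    df = pd.read_csv(path)
    needed = {"plot_id", "sapling_count", "sapling_area_m2"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(r.plot_id): (int(r.sapling_count), float(r.sapling_area_m2))
        for r in df.itertuples()
    }
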