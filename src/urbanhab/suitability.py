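"""Suitability classification, area/change accounting, centroids, site screening.

Logistic suitability surfaces are binned into four classes with left-closed,
right-open intervals and a closed top bin:

    unsuitable [0, 0.1) → 0,  low [0.1, 0.3) → 1,
    medium [0.3, 0.5) → 2,    high [0.5, 1.0] → 3.

Class areas are cell counts × the constant per-cell km².  Change accounting
compares scenario rows against a baseline row; the total-suitable change is
reported as −Δ(unsuitable), which equals Δ(low+medium+high) whenever row
totals agree exactly and stays consistent with published, rounded tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet, haversine_km
from .raster_io import Grid, cell_area_km2

__all__ = [
    "CLASS_NAMES",
    "SuitabilityMap",
    "ClassAreaTable",
    "ChangeSummary",
    "classify",
    "class_areas",
    "change_summary",
    "centroid_displacement",
    "screen_sites",
    "reference_class_areas",
]

CLASS_NAMES = ("unsuitable", "low", "medium", "high")
_BIN_EDGES = np.array([0.1, 0.3, 0.5])


@dataclass
class SuitabilityMap:
    """Grid of class codes {0,1,2,3} plus a (period, scenario) label."""

    grid: Grid
    label: str = ""


def classify(suitability: Grid, label: str = "") -> SuitabilityMap:
    """Bin a logistic suitability surface into the four classes."""
    vals = suitability.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.full(suitability.values.shape, np.nan)
    m = suitability.mask
    codes[m] = np.digitize(suitability.values[m], _BIN_EDGES)
    return SuitabilityMap(Grid(suitability.header, codes), label)


def class_areas(smap: SuitabilityMap) -> dict[str, float]:
    """km² per class (masked cells excluded)."""
    area = cell_area_km2(smap.grid.header)
    codes = smap.grid.valid_values().astype(int)
    return {name: float((codes == k).sum() * area) for k, name in enumerate(CLASS_NAMES)}


@dataclass
class ClassAreaTable:
    """Per-(period, scenario) class areas in km², Table-style bookkeeping."""

    rows: pd.DataFrame   # index (period, scenario); columns CLASS_NAMES
    total_km2: float

    @classmethod
    def from_maps(cls, maps: dict[tuple[str, str], SuitabilityMap]) -> "ClassAreaTable":
        data = {key: class_areas(m) for key, m in maps.items()}
        df = pd.DataFrame(data).T
        df.index = pd.MultiIndex.from_tuples(df.index, names=["period", "scenario"])
        totals = df.sum(axis=1)
        total = float(totals.iloc[0])
        if not np.allclose(totals, total, rtol=1e-9, atol=0):
            raise ValueError("class-area rows have inconsistent totals")
        return cls(df[list(CLASS_NAMES)], total)

    @classmethod
    def from_csv(cls, path: str | Path, total_km2: float | None = None) -> "ClassAreaTable":
        df = pd.read_csv(path)
        required = {"period", "scenario", *CLASS_NAMES}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df.set_index(["period", "scenario"])[list(CLASS_NAMES)].astype(float)
        if total_km2 is None:
            total_km2 = float(df.sum(axis=1).iloc[0])
        return cls(df, total_km2)

    def to_csv(self, path: str | Path) -> None:
        self.rows.reset_index().to_csv(path, index=False)

    def shares_percent(self, key: tuple[str, str], decimals: int = 1) -> dict[str, float]:
        """Class areas as % of the table total, rounded to printing precision."""
        row = self.rows.loc[key]
        return {name: round(100.0 * float(row[name]) / self.total_km2, decimals)
                for name in CLASS_NAMES}


@dataclass
class ChangeSummary:
    baseline_key: tuple[str, str]
    deltas: pd.DataFrame          # per-row per-class change vs baseline (km²)
    suitable_change: pd.Series    # per-row Δ total-suitable = −Δ unsuitable
    extremes: pd.DataFrame        # per-class min/max area across scenario rows


def change_summary(table: ClassAreaTable, baseline_key: tuple[str, str],
                   total_tolerance_km2: float | None = None) -> ChangeSummary:
    """Per-class area changes of every scenario row versus the baseline row.

    Row totals must agree within ``total_tolerance_km2`` (default
    1e-6 × total; pass a looser absolute value, e.g. 0.02 km², for tables
    digitised from rounded print).
    """
    if baseline_key not in table.rows.index:
        raise KeyError(f"baseline row {baseline_key} not in table")
    if total_tolerance_km2 is None:
        total_tolerance_km2 = 1e-6 * table.total_km2
    totals = table.rows.sum(axis=1)
    off = (totals - totals.loc[baseline_key]).abs()
    if (off > total_tolerance_km2).any():
        bad = off[off > total_tolerance_km2]
        raise ValueError(f"row totals differ from baseline beyond tolerance: {dict(bad)}")
    base = table.rows.loc[baseline_key]
    scen = table.rows.drop(index=baseline_key)
    deltas = scen - base
    suitable_change = -(scen["unsuitable"] - base["unsuitable"])
    extremes = pd.DataFrame({
        "min": scen.min(), "min_row": scen.idxmin(),
        "max": scen.max(), "max_row": scen.idxmax(),
    })
    return ChangeSummary(baseline_key, deltas, suitable_change, extremes)


def centroid_displacement(map_a: SuitabilityMap, map_b: SuitabilityMap, class_code: int
                          ) -> tuple[tuple[float, float], tuple[float, float], float, float]:
    """Centroid shift of one class between two maps.

    Centroids are unweighted means of the cell-centre lon/lat of the class's
    cells; returns ((lon_a, lat_a), (lon_b, lat_b), distance_km,
    bearing degrees clockwise from north, a → b).
    """
    def _centroid(smap: SuitabilityMap) -> tuple[float, float]:
        rows, cols = np.nonzero(smap.grid.values == class_code)
        if rows.size == 0:
            raise ValueError(f"class {class_code} absent from map {smap.label!r}")
        lon, lat = smap.grid.header.cell_center(rows, cols)
        return float(lon.mean()), float(lat.mean())

    a = _centroid(map_a)
    b = _centroid(map_b)
    dist = float(haversine_km(a[0], a[1], b[0], b[1]))
    lon1, lat1, lon2, lat2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    y = math.sin(lon2 - lon1) * math.cos(lat2)
    x = (math.cos(lat1) * math.sin(lat2)
         - math.sin(lat1) * math.cos(lat2) * math.cos(lon2 - lon1))
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    return a, b, dist, bearing


def screen_sites(sites: OccurrenceSet, smap: SuitabilityMap, min_class: int = 3
                 ) -> pd.DataFrame:
    """Flag sites whose containing cell is below ``min_class``.

    Returns one row per site with its class code and status: ``ok``,
    ``flagged`` (class < min_class) or ``off_grid`` (outside the grid or on a
    masked cell — listed, never silently dropped).
    """
    df = sites.records
    h = smap.grid.header
    row, col = h.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = h.in_bounds(row, col)
    codes = np.full(len(df), np.nan)
    codes[inside] = smap.grid.values[row[inside], col[inside]]
    status = np.where(~np.isfinite(codes), "off_grid",
                      np.where(codes < min_class, "flagged", "ok"))
    out = df.copy()
    out["class_code"] = codes
    out["status"] = status
    return out


def reference_class_areas() -> ClassAreaTable:
    """The bundled published class-area table for the Kunming urban core
    (baseline 1970–2000 plus three emission pathways × two future periods),
    against a printed total of 459 km²."""
    with resources.files("urbanhab.data").joinpath("kunming_class_areas.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index(["period", "scenario"])[list(CLASS_NAMES)].astype(float)
    return ClassAreaTable(df, 459.0)
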