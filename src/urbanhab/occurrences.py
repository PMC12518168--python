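"""Occurrence record handling: load, QC, spatial thinning, splits, covariates."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import LayerStack

__all__ = [
    "OccurrenceSet",
    "CovariateTable",
    "haversine_km",
    "load_occurrences",
    "thin_by_distance",
    "split_train_test",
    "extract_covariates",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
REQUIRED_COLUMNS = ("species", "lon", "lat")


@dataclass
class OccurrenceSet:
    """Ordered occurrence records plus QC bookkeeping."""

    records: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a WGS84 mean-radius sphere."""
    lon1, lat1 = np.radians(lon1), np.radians(lat1)
    lon2, lat2 = np.radians(lon2), np.radians(lat2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def load_occurrences(path: str | Path) -> OccurrenceSet:
    """Load a `species,lon,lat[,source_site]` CSV, dropping rows whose
    coordinates are unparseable or outside [-180,180]×[-90,90]."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n_raw = len(df)
    df = df.copy()
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        df["lon"].notna() & df["lat"].notna()
        & df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    )
    dropped = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    if df.empty:
        log.warning("%s: no valid occurrence records", path)
    return OccurrenceSet(df, {"loaded": n_raw, "dropped_invalid_coords": dropped})


def thin_by_distance(occ: OccurrenceSet, radius_km: float = 1.0) -> OccurrenceSet:
    """Greedy input-order spatial thinning.

    A record is kept iff its haversine distance to every previously kept
    record is >= radius_km; the kept set therefore satisfies the pairwise
    minimum-distance invariant, and the operation is idempotent.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    df = occ.records
    kept_lon: list[float] = []
    kept_lat: list[float] = []
    keep_idx: list[int] = []
    for i, (lon, lat) in enumerate(zip(df["lon"].to_numpy(), df["lat"].to_numpy())):
        if kept_lon:
            d = haversine_km(np.array(kept_lon), np.array(kept_lat), lon, lat)
            if (d < radius_km).any():
                continue
        kept_lon.append(lon)
        kept_lat.append(lat)
        keep_idx.append(i)
    provenance = dict(occ.provenance)
    provenance["dropped_thinning"] = provenance.get("dropped_thinning", 0) + (len(df) - len(keep_idx))
    return OccurrenceSet(df.iloc[keep_idx].reset_index(drop=True), provenance)


def split_train_test(occ: OccurrenceSet, train_fraction: float = 0.75,
                     seed: int | None = None, stratify_by: str | None = None
                     ) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint/exhaustive split; train size = round(fraction · n).

    With ``stratify_by`` set (e.g. ``source_site``), the rounding is applied
    within each stratum.  Rounding is Python's round-half-even.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    df = occ.records
    if len(df) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)

    def _pick(index: np.ndarray) -> np.ndarray:
        perm = rng.permutation(index)
        return perm[: int(round(train_fraction * len(index)))]

    if stratify_by is None:
        train_idx = _pick(np.arange(len(df)))
    else:
        if stratify_by not in df.columns:
            raise ValueError(f"stratification column {stratify_by!r} not present")
        train_idx = np.concatenate([
            _pick(np.flatnonzero(df[stratify_by].to_numpy() == level))
            for level in pd.unique(df[stratify_by])
        ]) if len(df) else np.array([], dtype=int)
    in_train = np.zeros(len(df), dtype=bool)
    in_train[train_idx] = True
    train = OccurrenceSet(df[in_train].reset_index(drop=True), dict(occ.provenance))
    test = OccurrenceSet(df[~in_train].reset_index(drop=True), dict(occ.provenance))
    return train, test


@dataclass
class CovariateTable:
    """Per-point environmental covariates (containing-cell extraction)."""

    table: pd.DataFrame
    n_dropped_off_grid: int
    n_dropped_masked: int


def extract_covariates(occ: OccurrenceSet, stack: LayerStack) -> CovariateTable:
    """Nearest-(containing-)cell covariate extraction.

    Points on the shared-invalid mask or outside the grid are dropped and
    counted.  Cell assignment uses half-open cells with inclusive west/north
    edges (see GridHeader.cell_index).
    """
    df = occ.records
    h = stack.header
    row, col = h.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = h.in_bounds(row, col)
    mask = stack.shared_mask
    valid = inside.copy()
    valid[inside] = mask[row[inside], col[inside]]
    n_off = int((~inside).sum())
    n_masked = int(inside.sum() - valid.sum())
    if not valid.any():
        raise ValueError("all occurrence points fall outside the valid grid")
    r, c = row[valid], col[valid]
    out = pd.DataFrame({name: stack.grids[name].values[r, c] for name in stack.names})
    out["row"] = r
    out["col"] = c
    out.index = df.index[valid]
    return CovariateTable(out, n_off, n_masked)
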