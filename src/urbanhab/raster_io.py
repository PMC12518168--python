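"""Gridded raster primitives.

Every spatial product in the pipeline travels as a :class:`Grid`: an ESRI
ASCII-style georeferenced array with a lower-left corner origin, square cells
in decimal degrees, and NaN as the canonical in-memory nodata value.  Row 0 is
the northernmost row, matching the on-disk ESRI convention.  Co-registered
sets of layers (the environmental variables of one period or scenario) are
bundled into a :class:`LayerStack`, whose shared mask is the intersection of
the per-layer valid masks.

Cell areas use an equal-area cosine approximation (one constant km² per cell,
evaluated at the domain-centre latitude).  For city-scale extents (≈0.5°) the
error is far below the class-area differences the pipeline reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridHeader",
    "Grid",
    "LayerStack",
    "GridFormatError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "stack_layers",
    "cell_area_km2",
]

#: kilometres per degree of latitude / of longitude at the equator (WGS84 mean)
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

_HEADER_TOL = 1e-9


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid file."""


class AlignmentError(ValueError):
    """Layers do not share one grid geometry."""


@dataclass(frozen=True)
class GridHeader:
    """Geometry of a georeferenced grid (lower-left corner convention)."""

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.ncols}x{self.nrows}")
        if not self.cellsize > 0:
            raise ValueError(f"cellsize must be > 0, got {self.cellsize}")

    @property
    def ytop(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def aligned(self, other: "GridHeader", tol: float = _HEADER_TOL) -> bool:
        return not self.mismatched_fields(other, tol)

    def mismatched_fields(self, other: "GridHeader", tol: float = _HEADER_TOL) -> list[str]:
        out = []
        if self.ncols != other.ncols:
            out.append("ncols")
        if self.nrows != other.nrows:
            out.append("nrows")
        for name in ("xll", "yll", "cellsize", "nodata_value"):
            if abs(getattr(self, name) - getattr(other, name)) > tol:
                out.append(name)
        return out

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """Longitude/latitude of cell centres for (row, col) indices."""
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def cell_index(self, lon: np.ndarray, lat: np.ndarray):
        """Containing-cell (row, col) with half-open cells.

        West and north cell edges are inclusive; a point on the extreme south
        or east boundary of the domain therefore falls outside the grid.
        Returned indices may be out of range — callers screen with
        :meth:`in_bounds`.
        """
        col = np.floor((np.asarray(lon, dtype=float) - self.xll) / self.cellsize).astype(int)
        row = np.floor((self.ytop - np.asarray(lat, dtype=float)) / self.cellsize).astype(int)
        return row, col

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)


@dataclass
class Grid:
    """A raster layer: header plus an nrows×ncols float array, NaN = nodata."""

    header: GridHeader
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.header.nrows, self.header.ncols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} does not match header {expected}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where the cell holds data)."""
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(self.header, np.asarray(values, dtype=float))

    def equals(self, other: "Grid") -> bool:
        if not self.header.aligned(other.header):
            return False
        a, b = self.values, other.values
        return bool(np.array_equal(a, b, equal_nan=True))


@dataclass
class LayerStack:
    """Named, co-registered set of grids (one period or scenario)."""

    names: list[str]
    grids: dict[str, Grid]
    categorical_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        for name in self.names:
            if name not in self.grids:
                raise ValueError(f"missing grid for layer {name!r}")
        self.categorical_flags = {n: bool(self.categorical_flags.get(n, False)) for n in self.names}
        ref = self.grids[self.names[0]].header
        for name in self.names[1:]:
            bad = ref.mismatched_fields(self.grids[name].header)
            if bad:
                raise AlignmentError(
                    f"layer {name!r} is not aligned with {self.names[0]!r}: "
                    f"mismatched fields {bad}"
                )

    @property
    def header(self) -> GridHeader:
        return self.grids[self.names[0]].header

    @property
    def shared_mask(self) -> np.ndarray:
        mask = np.ones((self.header.nrows, self.header.ncols), dtype=bool)
        for name in self.names:
            mask &= self.grids[name].mask
        return mask

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.names if not self.categorical_flags[n]]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n in self.names if self.categorical_flags[n]]

    def table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Per-cell covariate table over the (shared) valid mask.

        Returns a DataFrame with one column per layer plus ``row``/``col``
        integer cell indices — the common currency handed to the model.
        """
        if mask is None:
            mask = self.shared_mask
        rows, cols = np.nonzero(mask)
        data = {name: self.grids[name].values[rows, cols] for name in self.names}
        out = pd.DataFrame(data)
        out["row"] = rows
        out["col"] = cols
        return out

    def subset(self, names: Sequence[str]) -> "LayerStack":
        missing = [n for n in names if n not in self.grids]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return LayerStack(
            list(names),
            {n: self.grids[n] for n in names},
            {n: self.categorical_flags[n] for n in names},
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter",
    "cellsize", "nodata_value",
}


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    Header keys are case-insensitive; ``XLLCENTER``/``YLLCENTER`` headers are
    converted to the corner convention (centre − cellsize/2).  Cells equal to
    the nodata value become NaN.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header_raw: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            try:
                header_raw[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: malformed header line {i + 1}: {line!r}") from exc
            data_start = i + 1
        else:
            break

    for required in ("ncols", "nrows", "cellsize"):
        if required not in header_raw:
            raise GridFormatError(f"{path}: missing header key {required!r}")
    if not ({"xllcorner", "xllcenter"} & header_raw.keys()):
        raise GridFormatError(f"{path}: missing header key 'xllcorner' (or 'xllcenter')")
    if not ({"yllcorner", "yllcenter"} & header_raw.keys()):
        raise GridFormatError(f"{path}: missing header key 'yllcorner' (or 'yllcenter')")

    cellsize = header_raw["cellsize"]
    xll = header_raw.get("xllcorner", header_raw.get("xllcenter", 0.0) - cellsize / 2.0)
    yll = header_raw.get("yllcorner", header_raw.get("yllcenter", 0.0) - cellsize / 2.0)
    header = GridHeader(
        ncols=int(header_raw["ncols"]),
        nrows=int(header_raw["nrows"]),
        xll=xll,
        yll=yll,
        cellsize=cellsize,
        nodata_value=header_raw.get("nodata_value", -9999.0),
    )

    tokens: list[str] = []
    for line in lines[data_start:]:
        tokens.extend(line.split())
    expected = header.nrows * header.ncols
    if len(tokens) != expected:
        raise GridFormatError(
            f"{path}: expected {expected} data values ({header.nrows}x{header.ncols}), "
            f"found {len(tokens)}"
        )
    try:
        values = np.array(tokens, dtype=float).reshape(header.nrows, header.ncols)
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric data value") from exc
    values[values == header.nodata_value] = np.nan
    return Grid(header, values)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; read_ascii_grid(write(g)) is the identity.

    Values are written with shortest round-trip float formatting, so the
    read-back grid is bit-identical.
    """
    h = grid.header
    path = Path(path)
    out = grid.values.copy()
    out[~grid.mask] = h.nodata_value
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {h.ncols}\n")
        fh.write(f"nrows {h.nrows}\n")
        fh.write(f"xllcorner {_fmt(h.xll)}\n")
        fh.write(f"yllcorner {_fmt(h.yll)}\n")
        fh.write(f"cellsize {_fmt(h.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(h.nodata_value)}\n")
        for r in range(h.nrows):
            fh.write(" ".join(_fmt(v) for v in out[r]))
            fh.write("\n")


def _fmt(v: float) -> str:
    return repr(float(v))


def read_stack(
    directory: str | Path,
    names: Sequence[str] | None = None,
    categorical: Iterable[str] = (),
) -> LayerStack:
    """Read every ``<name>.asc`` in a directory into an aligned stack."""
    directory = Path(directory)
    if names is None:
        names = sorted(p.stem for p in directory.glob("*.asc"))
    if not names:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    grids = {n: read_ascii_grid(directory / f"{n}.asc") for n in names}
    return stack_layers(grids, categorical, names=list(names))


def stack_layers(
    grids: Mapping[str, Grid],
    categorical_names: Iterable[str] = (),
    names: Sequence[str] | None = None,
) -> LayerStack:
    """Bundle named grids into a LayerStack, verifying alignment."""
    if not grids:
        raise ValueError("at least one grid is required")
    if names is None:
        names = list(grids.keys())
    categorical = set(categorical_names)
    unknown = categorical - set(names)
    if unknown:
        raise ValueError(f"categorical names not in stack: {sorted(unknown)}")
    return LayerStack(list(names), dict(grids), {n: n in categorical for n in names})


def cell_area_km2(header: GridHeader) -> float:
    """Constant per-cell area in km² (equal-area cosine approximation).

    area = (cellsize · 111.320 · cos φc) × (cellsize · 110.574), with φc the
    domain-centre latitude.
    """
    phi_c = header.yll + header.nrows * header.cellsize / 2.0
    if abs(phi_c) >= 90.0:
        raise ValueError(f"domain-centre latitude {phi_c} out of range (-90, 90)")
    ew = header.cellsize * KM_PER_DEG_LON_EQ * math.cos(math.radians(phi_c))
    ns = header.cellsize * KM_PER_DEG_LAT
    return ew * ns
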