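"""Ground-truth scenario generator.

Builds spatially autocorrelated environmental surfaces with controlled
pairwise correlations, a known species–environment relationship (a Gibbs /
exponential-family law over cells, the same family the estimator fits),
presence samples drawn from that law, and labelled "future" layer stacks
obtained by additive/multiplicative shifts of the baseline.  Everything is
deterministic under a single integer seed, so each downstream stage has a
known answer to recover.

Smooth fields are Gaussian-kernel-smoothed seeded white noise, standardised
to zero mean / unit variance over the grid.  Cross-variable correlation is
induced by linearly mixing empirically orthonormalised latent fields with the
Cholesky factor of the target correlation matrix, which makes the *sample*
correlations of the generated layers match the target exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster_io import Grid, GridHeader, LayerStack, stack_layers, write_ascii_grid

__all__ = [
    "TruthModel",
    "ScenarioConfig",
    "SyntheticScenario",
    "make_random_field",
    "make_terrain",
    "horn_slope_aspect",
    "build_scenario",
    "sample_presences",
    "gibbs_probabilities",
    "write_scenario",
    "demo_config",
    "demo_scenario",
]

_M_PER_DEG_LAT = 110574.0
_M_PER_DEG_LON_EQ = 111320.0


@dataclass
class TruthModel:
    """The known species–environment relationship behind a scenario.

    ``weights`` act on the raw (standardised) variable values; presences are
    drawn with probability ∝ exp(Σ w_v x_v) over valid cells ("gibbs" kind)
    or ∝ sigmoid(Σ w_v x_v) (the deliberately misspecified "logistic" kind).
    """

    variable_names: list[str]
    weights: dict[str, float]
    kind: str = "gibbs"
    scenario_shifts: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("gibbs", "logistic"):
            raise ValueError(f"unknown truth kind {self.kind!r}")
        for name, w in self.weights.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite truth weight for {name!r}")


@dataclass
class ScenarioConfig:
    """Generator settings; defaults give a compact strong-signal study."""

    nrows: int = 100
    ncols: int = 100
    xll: float = 102.55
    yll: float = 24.85
    cellsize: float = 0.0055
    variables: tuple[str, ...] = ("bio7", "bio17", "bio2")
    smoothness: float = 5.0
    #: target pairwise correlation matrix (len(variables) square); None = identity
    correlation: np.ndarray | None = None
    weights: dict[str, float] = field(default_factory=lambda: {"bio7": 4.0, "bio17": -3.0, "bio2": 2.5})
    truth_kind: str = "gibbs"
    #: label -> {variable: (additive, multiplicative)} perturbations
    scenario_shifts: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: optional categorical layer (name, n_classes), e.g. a land-use mosaic
    categorical: tuple[str, int] | None = None
    n_presences: int = 5000
    duplicate_pairs: int = 0

    def header(self) -> GridHeader:
        return GridHeader(ncols=self.ncols, nrows=self.nrows, xll=self.xll,
                          yll=self.yll, cellsize=self.cellsize)


@dataclass
class SyntheticScenario:
    baseline_stack: LayerStack
    future_stacks: dict[str, LayerStack]
    occurrences: pd.DataFrame
    truth: TruthModel
    seed: int


def make_random_field(header: GridHeader, smoothness: float, seed: int) -> Grid:
    """Zero-mean unit-variance smooth Gaussian field; deterministic in seed.

    ``smoothness`` is the Gaussian kernel length-scale in cells; 0 gives
    white noise.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((header.nrows, header.ncols))
    if smoothness > 0:
        z = gaussian_filter(z, sigma=smoothness, mode="reflect")
    z = (z - z.mean()) / z.std()
    return Grid(header, z)


def horn_slope_aspect(elevation: Grid) -> tuple[Grid, Grid]:
    """Slope (degrees) and aspect (degrees clockwise from north) by Horn's
    3×3 finite-difference method; flat cells get aspect −1.

    Cell spacing is converted to metres at the domain-centre latitude, so
    slope is rise-over-run of elevation in metres.
    """
    h = elevation.header
    if h.nrows < 3 or h.ncols < 3:
        raise ValueError("terrain grids must be at least 3x3")
    phi_c = math.radians(h.yll + h.nrows * h.cellsize / 2.0)
    dx = h.cellsize * _M_PER_DEG_LON_EQ * math.cos(phi_c)
    dy = h.cellsize * _M_PER_DEG_LAT
    z = np.pad(elevation.values, 1, mode="edge")
    # neighbours: z[r-1,c-1] .. z[r+1,c+1] relative to the centre cell
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx)   # eastward
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dy)   # northward
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0             # downslope bearing
    flat = (np.abs(gx) < 1e-12) & (np.abs(gy) < 1e-12)
    aspect[flat] = -1.0
    return Grid(h, slope), Grid(h, aspect)


def make_terrain(header: GridHeader, seed: int,
                 base_elevation: float = 1950.0, relief: float = 80.0
                 ) -> tuple[Grid, Grid, Grid]:
    """Elevation (smooth field + ridges), slope and aspect grids."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    broad = make_random_field(header, max(header.nrows, header.ncols) / 12.0, int(s1)).values
    ridges = np.abs(make_random_field(header, max(header.nrows, header.ncols) / 25.0, int(s2)).values)
    elev = Grid(header, base_elevation + relief * broad + 0.5 * relief * ridges)
    slope, aspect = horn_slope_aspect(elev)
    return elev, slope, aspect


def _orthonormal_latents(header: GridHeader, k: int, smoothness: float,
                         rng: np.random.Generator) -> np.ndarray:
    """k exactly-decorrelated unit-variance latent fields, flattened (ncell, k)."""
    n = header.nrows * header.ncols
    fields = np.column_stack([
        make_random_field(header, smoothness, int(rng.integers(0, 2**31 - 1))).values.ravel()
        for _ in range(k)
    ])
    fields -= fields.mean(axis=0)
    q, r = np.linalg.qr(fields)
    # fix sign so each latent correlates positively with its source field
    q *= np.sign(np.diag(r))
    return q * math.sqrt(n)


def build_scenario(config: ScenarioConfig, seed: int) -> SyntheticScenario:
    """Generate a full ground-truth scenario from a config and seed."""
    header = config.header()
    names = list(config.variables)
    if len(names) < 1:
        raise ValueError("at least one continuous variable is required")
    k = len(names)
    corr = np.eye(k) if config.correlation is None else np.asarray(config.correlation, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(seed)
    latents = _orthonormal_latents(header, k, config.smoothness, rng)
    mixed = latents @ chol.T
    # re-standardise (mixing preserves unit variance exactly, this is belt and braces)
    mixed = (mixed - mixed.mean(axis=0)) / mixed.std(axis=0)

    grids = {name: Grid(header, mixed[:, i].reshape(header.nrows, header.ncols))
             for i, name in enumerate(names)}
    categorical: list[str] = []
    if config.categorical is not None:
        cat_name, n_classes = config.categorical
        base = make_random_field(header, config.smoothness, int(rng.integers(0, 2**31 - 1))).values
        edges = np.quantile(base, np.linspace(0, 1, n_classes + 1)[1:-1])
        grids[cat_name] = Grid(header, np.digitize(base, edges).astype(float))
        names = names + [cat_name]
        categorical = [cat_name]

    baseline = stack_layers(grids, categorical, names=names)

    missing = [v for v in config.weights if v not in names]
    if missing:
        raise ValueError(f"truth weights reference unknown variables: {missing}")
    truth = TruthModel(
        variable_names=names,
        weights=dict(config.weights),
        kind=config.truth_kind,
        scenario_shifts={lbl: dict(shifts) for lbl, shifts in config.scenario_shifts.items()},
    )

    future: dict[str, LayerStack] = {}
    for label, shifts in config.scenario_shifts.items():
        shifted = {}
        for name in names:
            g = baseline.grids[name]
            if name in categorical:
                shifted[name] = g.copy_with(g.values.copy())
                continue
            add, mul = shifts.get(name, (0.0, 1.0))
            shifted[name] = g.copy_with(g.values * mul + add)
        future[label] = stack_layers(shifted, categorical, names=names)

    scenario = SyntheticScenario(baseline, future, pd.DataFrame(), truth, seed)
    scenario.occurrences = sample_presences(
        scenario, config.n_presences, int(rng.integers(0, 2**31 - 1)),
        duplicate_pairs=config.duplicate_pairs,
    )
    return scenario


def gibbs_probabilities(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-valid-cell sampling probabilities of the truth (sum to 1).

    Returns (probabilities, rows, cols) over the baseline shared mask.
    """
    stack = scenario.baseline_stack
    mask = stack.shared_mask
    rows, cols = np.nonzero(mask)
    eta = np.zeros(rows.size)
    for name, w in scenario.truth.weights.items():
        eta += w * stack.grids[name].values[rows, cols]
    if scenario.truth.kind == "gibbs":
        eta -= eta.max()
        p = np.exp(eta)
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
    p = p / p.sum()
    return p, rows, cols


def sample_presences(scenario: SyntheticScenario, n: int, seed: int,
                     duplicate_pairs: int = 0, replace: bool = True,
                     species: str = "synthetic_butterfly") -> pd.DataFrame:
    """Draw presence points from the scenario's truth law.

    Cells are drawn with the Gibbs (or logistic) truth probabilities; points
    are jittered uniformly within their cell.  ``duplicate_pairs`` appends
    that many exact coordinate duplicates of already-sampled points, for
    deduplication tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p, rows, cols = gibbs_probabilities(scenario)
    if not replace and n > rows.size:
        raise ValueError(f"cannot sample {n} distinct cells from {rows.size} valid cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=replace, p=p)
    h = scenario.baseline_stack.header
    u = rng.uniform(0, 1, size=n)
    v = rng.uniform(0, 1, size=n)
    lon = h.xll + (cols[idx] + u) * h.cellsize
    lat = h.yll + (h.nrows - rows[idx] - v) * h.cellsize
    df = pd.DataFrame({"species": species, "lon": lon, "lat": lat})
    if duplicate_pairs > 0:
        dup_idx = rng.choice(n, size=duplicate_pairs, replace=False)
        df = pd.concat([df, df.iloc[dup_idx]], ignore_index=True)
    return df


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Write a scenario to disk: one .asc per layer per period, the
    occurrence CSV, and truth.json (weights, shifts, seed)."""
    directory = Path(directory)
    base_dir = directory / "baseline"
    base_dir.mkdir(parents=True, exist_ok=True)
    for name in scenario.baseline_stack.names:
        write_ascii_grid(scenario.baseline_stack.grids[name], base_dir / f"{name}.asc")
    for label, stack in scenario.future_stacks.items():
        d = directory / "scenarios" / label
        d.mkdir(parents=True, exist_ok=True)
        for name in stack.names:
            write_ascii_grid(stack.grids[name], d / f"{name}.asc")
    scenario.occurrences.to_csv(directory / "occurrences.csv", index=False)
    truth = scenario.truth
    payload = {
        "variable_names": truth.variable_names,
        "weights": truth.weights,
        "kind": truth.kind,
        "scenario_shifts": {lbl: {v: list(sh) for v, sh in shifts.items()}
                            for lbl, shifts in truth.scenario_shifts.items()},
        "seed": scenario.seed,
        "categorical": scenario.baseline_stack.categorical_names,
    }
    (directory / "truth.json").write_text(json.dumps(payload, indent=2))


def demo_config(nrows: int = 100, ncols: int = 100, n_presences: int = 5000) -> ScenarioConfig:
    """The bundled strong-signal study: three correlated climate-like fields
    with large truth weights, plus mild warming/drying shifts for two future
    periods under three emission pathways."""
    k = 3
    corr = np.eye(k)
    corr[0, 2] = corr[2, 0] = 0.3   # bio7 ~ bio2
    shifts = {}
    for period, scale in (("2021-2040", 1.0), ("2041-2060", 2.0)):
        for ssp, forcing in (("SSP1-2.6", 0.15), ("SSP2-4.5", 0.30), ("SSP5-8.5", 0.50)):
            shifts[f"{period}_{ssp}"] = {
                "bio7": (scale * forcing, 1.0),
                "bio17": (-0.5 * scale * forcing, 1.0),
                "bio2": (0.25 * scale * forcing, 1.0),
            }
    return ScenarioConfig(
        nrows=nrows, ncols=ncols,
        variables=("bio7", "bio17", "bio2"),
        correlation=corr,
        weights={"bio7": 4.0, "bio17": -3.0, "bio2": 2.5},
        scenario_shifts=shifts,
        n_presences=n_presences,
    )


def demo_scenario(seed: int = 0, **kwargs) -> SyntheticScenario:
    return build_scenario(demo_config(**kwargs), seed)
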