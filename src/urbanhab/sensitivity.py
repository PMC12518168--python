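"""AHP weighting and the weighted ecological-sensitivity index (EI).

The ecological sensitivity of a cell is a weighted sum of standardised
indicator layers, EI_i = Σ_j Y_ij · W_j with Y_ij ∈ [0,1] and the effective
weights W_j = W_group · w_factor summing to 1, so EI ∈ [0,1].  Weights can be
supplied directly (a published weighting table) or derived from pairwise
comparison matrices by the principal-eigenvector Analytic Hierarchy Process
with Saaty's consistency-ratio gate (CR < 0.1).  EI surfaces are zoned into
five sensitivity levels (insensitive … extremely sensitive), by equal
0.2-wide intervals by default or exact Jenks natural breaks on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_io import AlignmentError, Grid, cell_area_km2
from .suitability import CLASS_NAMES, SuitabilityMap

__all__ = [
    "SAATY_RANDOM_INDEX",
    "PairwiseMatrix",
    "AhpResult",
    "ahp_weights",
    "WeightTree",
    "IndicatorLayer",
    "standardize",
    "ei_index",
    "classify_sensitivity",
    "jenks_breaks",
    "overlay_with_suitability",
    "SensitivityMap",
    "reference_weight_tree",
]

#: Saaty random-consistency index by matrix order
SAATY_RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                      6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

LEVEL_NAMES = ("insensitive", "mild", "moderate", "high", "extreme")


@dataclass
class PairwiseMatrix:
    """A positive reciprocal pairwise-comparison matrix."""

    names: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        n = len(self.names)
        if a.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n}")
        if not (a > 0).all():
            raise ValueError("pairwise matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("pairwise matrix must have unit diagonal")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise ValueError("pairwise matrix must be reciprocal (a_ij = 1/a_ji)")
        self.entries = a

    @classmethod
    def from_weights(cls, names: Sequence[str], weights: Sequence[float]) -> "PairwiseMatrix":
        """Perfectly consistent matrix a_ij = w_i / w_j."""
        w = np.asarray(weights, dtype=float)
        return cls(list(names), w[:, None] / w[None, :])


@dataclass
class AhpResult:
    names: list[str]
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    acceptable: bool


def ahp_weights(matrix: PairwiseMatrix) -> AhpResult:
    """Principal-eigenvector AHP weights with Saaty's consistency check.

    CI = (λmax − n)/(n − 1), CR = CI/RI(n); CR < 0.1 is flagged acceptable.
    """
    n = len(matrix.names)
    if n > 9:
        raise ValueError("AHP supported for matrices of order 1..9")
    vals, vecs = np.linalg.eig(matrix.entries)
    k = int(np.argmax(vals.real))
    lam = float(vals[k].real)
    w = np.abs(vecs[:, k].real)
    w = w / w.sum()
    ci = 0.0 if n == 1 else (lam - n) / (n - 1)
    ri = SAATY_RANDOM_INDEX[n]
    cr = 0.0 if ri == 0 else ci / ri
    return AhpResult(list(matrix.names), w, lam, ci, cr, cr < 0.1)


@dataclass
class WeightTree:
    """Hierarchical weights: groups (W_i) of factors (w_j), both summing to 1.

    Effective per-indicator weight is W_i·w_j; these sum to 1 across the
    whole tree.  ``tolerance`` loosens the sum checks for weights typed from
    rounded print.
    """

    groups: list[tuple[str, float, list[tuple[str, float]]]]
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        gsum = sum(w for _, w, _ in self.groups)
        if abs(gsum - 1.0) > self.tolerance:
            raise ValueError(f"group weights sum to {gsum}, expected 1")
        names = []
        for gname, _, factors in self.groups:
            fsum = sum(w for _, w in factors)
            if abs(fsum - 1.0) > self.tolerance:
                raise ValueError(f"factor weights in group {gname!r} sum to {fsum}")
            names.extend(n for n, _ in factors)
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique across groups")

    @classmethod
    def from_dict(cls, payload: Mapping, tolerance: float = 1e-6) -> "WeightTree":
        groups = [(g["name"], float(g["weight"]),
                   [(f["name"], float(f["weight"])) for f in g["factors"]])
                  for g in payload["groups"]]
        return cls(groups, tolerance)

    def effective_weights(self) -> dict[str, float]:
        out = {}
        for _, gw, factors in self.groups:
            for fname, fw in factors:
                out[fname] = gw * fw
        total = sum(out.values())
        # renormalise away printed-rounding residue so EI stays in [0,1]
        return {k: v / total for k, v in out.items()}


@dataclass
class IndicatorLayer:
    """A sensitivity indicator before standardisation.

    direction="benefit": larger raw values mean more sensitive;
    direction="cost": larger raw values mean less sensitive.  Categorical
    indicators carry an explicit value → score map instead.
    """

    grid: Grid
    direction: str = "benefit"
    categorical_scores: dict[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise ValueError(f"direction must be 'benefit' or 'cost', got {self.direction!r}")


def standardize(layer: IndicatorLayer) -> Grid:
    """Min-max standardise an indicator to [0,1] over its valid cells."""
    g = layer.grid
    out = np.full(g.values.shape, np.nan)
    m = g.mask
    x = g.values[m]
    if layer.categorical_scores is not None:
        levels = np.unique(x)
        missing = [v for v in levels if float(v) not in layer.categorical_scores]
        if missing:
            raise ValueError(f"categorical values missing from score map: {missing}")
        top = max(layer.categorical_scores.values())
        lut = {v: s / top for v, s in layer.categorical_scores.items()}
        out[m] = np.vectorize(lambda v: lut[float(v)])(x)
        return Grid(g.header, out)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        warnings.warn("constant indicator layer; standardised to 0.5", stacklevel=2)
        out[m] = 0.5
        return Grid(g.header, out)
    y = (x - lo) / (hi - lo)
    if layer.direction == "cost":
        y = 1.0 - y
    out[m] = y
    return Grid(g.header, out)


def ei_index(layers: Mapping[str, Grid], tree: WeightTree) -> Grid:
    """Weighted ecological-sensitivity index over the shared valid mask."""
    weights = tree.effective_weights()
    missing = [name for name in weights if name not in layers]
    if missing:
        raise ValueError(f"no standardised layer supplied for weighted factor(s) {missing}")
    ref = None
    for name in weights:
        g = layers[name]
        if ref is None:
            ref = g
        elif not ref.header.aligned(g.header):
            raise AlignmentError(f"indicator layer {name!r} is not aligned")
        vals = g.valid_values()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError(f"layer {name!r} is not standardised to [0,1]")
    mask = np.ones((ref.header.nrows, ref.header.ncols), dtype=bool)
    for name in weights:
        mask &= layers[name].mask
    ei = np.full(mask.shape, np.nan)
    acc = np.zeros(mask.shape)
    for name, w in weights.items():
        acc += np.where(mask, layers[name].values, 0.0) * w
    ei[mask] = np.clip(acc[mask], 0.0, 1.0)
    return Grid(ref.header, ei)


def jenks_breaks(values: np.ndarray, k: int) -> list[float]:
    """Exact Jenks natural breaks (dynamic programming, O(k·n²)).

    Returns the k−1 interior break values (upper bounds of the first k−1
    classes).  Intended for modest sample sizes; callers subsample large
    rasters first.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k values")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:   # cost of one class x[i:j]
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        cnt = j - i
        return s2 - s * s / cnt

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < cost[c, j]:
                    cost[c, j] = v
                    back[c, j] = i
    cuts = []
    j = n
    for c in range(k, 1, -1):
        i = back[c, j]
        cuts.append(float(x[i - 1]))
        j = i
    return sorted(cuts)


@dataclass
class SensitivityMap:
    ei: Grid
    levels: Grid


def classify_sensitivity(ei: Grid, method: str = "equal_interval",
                         seed: int | None = None, max_jenks_cells: int = 2000
                         ) -> SensitivityMap:
    """Zone an EI surface into the five sensitivity levels (codes 1..5).

    equal_interval: [0,0.2)→1 … [0.8,1.0]→5 (left-closed bins).
    jenks: exact natural breaks on the valid values (a seeded subsample of at
    most ``max_jenks_cells`` cells is used for break estimation on large
    rasters).
    """
    m = ei.mask
    vals = ei.values[m]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("EI values must lie in [0, 1]")
    if method == "equal_interval":
        edges = np.array([0.2, 0.4, 0.6, 0.8])
    elif method == "jenks":
        sample = vals
        if sample.size > max_jenks_cells:
            rng = np.random.default_rng(seed)
            sample = rng.choice(sample, size=max_jenks_cells, replace=False)
        edges = np.asarray(jenks_breaks(sample, 5))
    else:
        raise ValueError(f"unknown method {method!r}")
    levels = np.full(ei.values.shape, np.nan)
    levels[m] = np.digitize(vals, edges, right=method == "jenks") + 1
    return SensitivityMap(ei, Grid(ei.header, levels))


def overlay_with_suitability(sens: SensitivityMap, suit: SuitabilityMap) -> pd.DataFrame:
    """5×4 km² cross-tabulation of sensitivity level × suitability class."""
    if not sens.levels.header.aligned(suit.grid.header):
        raise AlignmentError("sensitivity and suitability maps are not aligned")
    area = cell_area_km2(suit.grid.header)
    both = sens.levels.mask & suit.grid.mask
    lv = sens.levels.values[both].astype(int)
    sc = suit.grid.values[both].astype(int)
    counts = np.zeros((5, 4))
    np.add.at(counts, (lv - 1, sc), 1.0)
    return pd.DataFrame(counts * area, index=list(LEVEL_NAMES), columns=list(CLASS_NAMES))


def reference_weight_tree(tolerance: float = 0.01) -> WeightTree:
    """The published Kunming ecological-sensitivity weighting: four groups
    (geological, climate, natural-resource, human-disturbance) with their
    indicator-factor weights, typed from rounded print (hence the loose
    tolerance)."""
    return WeightTree([
        ("geological", 0.18, [
            ("elevation", 0.34), ("slope", 0.21), ("aspect", 0.11),
            ("terrain_relief", 0.11), ("surface_incision_depth", 0.15),
            ("topographic_roughness", 0.08)]),
        ("climate", 0.17, [
            ("mean_temperature", 0.17), ("annual_mean_precipitation", 0.60),
            ("relative_humidity", 0.23)]),
        ("natural_resource", 0.31, [
            ("river_buffer", 0.21), ("lake_riparian_buffer", 0.18),
            ("soil_taxonomy", 0.11), ("land_use", 0.26),
            ("vegetation_coverage", 0.24)]),
        ("human_disturbance", 0.34, [
            ("distance_to_roads", 0.58), ("population_density", 0.42)]),
    ], tolerance=tolerance)
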