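"""Presence-background maximum-entropy species distribution model.

The estimator picks the distribution p over background cells that maximises
entropy subject to (soft) feature-expectation constraints — equivalently an
L1-regularised exponential-family (Gibbs) model.  With features f(x) ∈ [0,1]^d
and weights λ, the raw output is

    raw(x) = exp(λ·f(x)) / Z,       Z = Σ_b exp(λ·f(b))  over the N training
                                    background cells,

and fitting maximises the regularised training gain (log-likelihood
improvement over the uniform background model)

    G(λ) = (1/m) Σ_i λ·f(x_i) − log Z + log N − Σ_j β_j |λ_j|,

with per-feature β_j = β · s_j / √m (s_j = the feature's standard deviation
over the m presences, floored at 1e-3), so regularisation tightens with small
samples.  Optimisation is cyclic coordinate descent with soft-threshold
Newton steps and a backtracking line search, which makes G non-decreasing and
defines a per-step gain credit for each feature's source variable — the basis
of the percent-contribution accounting.

The logistic ("suitability") output is the entropy-anchored transform
logistic(x) = raw·e^H / (1 + raw·e^H) with H the entropy of the fitted raw
distribution; a cell that looks like a "typical" presence scores 0.5.  A
complementary log-log variant is available via ``output="cloglog"``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .occurrences import OccurrenceSet, extract_covariates
from .raster_io import Grid, LayerStack

__all__ = [
    "FeatureSpec",
    "FeatureDef",
    "FeatureMap",
    "MaxentModel",
    "EvalReport",
    "build_feature_map",
    "fit",
    "predict_raw",
    "predict_logistic",
    "auc",
    "tss",
    "evaluate",
    "spatial_cross_validate",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
    "ResponseCurve",
]

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "categorical")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to build, plus the regularisation multiplier."""

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: int = 10
    beta: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise ValueError("hinge_knots must be >= 2 when hinge features are enabled")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str
    variables: tuple[str, ...]
    knot: float | None = None      # hinge knot, in scaled [0,1] units
    category: float | None = None  # categorical indicator level


class FeatureMap:
    """Deterministic covariate-vector → feature-vector map, components in [0,1].

    Normalisation bounds (per-variable min/max) come from the training
    background only; out-of-range projection values are clamped to those
    bounds ("fade by clamping") and the clamp count recorded on
    ``last_clamped``.
    """

    def __init__(self, defs: list[FeatureDef], bounds: dict[str, tuple[float, float]],
                 categories: dict[str, list[float]],
                 background_means: dict[str, float], background_modes: dict[str, float]):
        self.defs = defs
        self.bounds = bounds
        self.categories = categories
        self.background_means = background_means
        self.background_modes = background_modes
        self.last_clamped = 0

    @property
    def n_features(self) -> int:
        return len(self.defs)

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.defs:
            for v in d.variables:
                seen.setdefault(v, None)
        return list(seen)

    def scaled(self, table: pd.DataFrame) -> dict[str, np.ndarray]:
        """Min-max scaled continuous variables, clamped to training bounds."""
        out = {}
        clamped = 0
        for var, (lo, hi) in self.bounds.items():
            x = np.asarray(table[var], dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite values in variable {var!r}")
            clamped += int(((x < lo) | (x > hi)).sum())
            x = np.clip(x, lo, hi)
            out[var] = (x - lo) / (hi - lo)
        self.last_clamped = clamped
        if clamped:
            log.info("clamped %d out-of-range covariate values to training bounds", clamped)
        return out

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        u = self.scaled(table)
        cols = np.empty((len(table), len(self.defs)))
        for k, d in enumerate(self.defs):
            if d.kind == "linear":
                cols[:, k] = u[d.variables[0]]
            elif d.kind == "quadratic":
                cols[:, k] = u[d.variables[0]] ** 2
            elif d.kind == "product":
                cols[:, k] = u[d.variables[0]] * u[d.variables[1]]
            elif d.kind == "hinge_forward":
                t = d.knot
                cols[:, k] = np.maximum(0.0, (u[d.variables[0]] - t) / (1.0 - t))
            elif d.kind == "hinge_reverse":
                t = d.knot
                cols[:, k] = np.maximum(0.0, (t - u[d.variables[0]]) / t)
            elif d.kind == "categorical":
                x = np.asarray(table[d.variables[0]], dtype=float)
                cols[:, k] = (x == d.category).astype(float)
            else:  # pragma: no cover
                raise AssertionError(d.kind)
        return cols

    def to_dict(self) -> dict:
        return {
            "defs": [{"name": d.name, "kind": d.kind, "variables": list(d.variables),
                      "knot": d.knot, "category": d.category} for d in self.defs],
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "categories": self.categories,
            "background_means": self.background_means,
            "background_modes": self.background_modes,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureMap":
        defs = [FeatureDef(d["name"], d["kind"], tuple(d["variables"]),
                           d.get("knot"), d.get("category")) for d in payload["defs"]]
        return cls(defs, {k: tuple(v) for k, v in payload["bounds"].items()},
                   {k: list(v) for k, v in payload["categories"].items()},
                   dict(payload["background_means"]), dict(payload["background_modes"]))


def build_feature_map(background: pd.DataFrame, spec: FeatureSpec,
                      categorical: Sequence[str] = (),
                      presence: pd.DataFrame | None = None,
                      variables: Sequence[str] | None = None) -> FeatureMap:
    """Construct the feature map from the training background.

    ``background``/``presence`` are covariate tables (one column per
    variable).  Continuous variables are min-max scaled on background bounds;
    hinge knots sit at background quantiles; categorical levels are the union
    observed in background and presences.  Constant variables contribute no
    features (warning).
    """
    if variables is None:
        variables = [c for c in background.columns if c not in ("row", "col")]
    categorical = [c for c in categorical if c in variables]
    continuous = [v for v in variables if v not in categorical]

    bounds: dict[str, tuple[float, float]] = {}
    means: dict[str, float] = {}
    modes: dict[str, float] = {}
    for var in continuous:
        x = np.asarray(background[var], dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            warnings.warn(f"variable {var!r} is constant over the background; "
                          "its features are dropped", stacklevel=2)
            continue
        bounds[var] = (lo, hi)
        means[var] = float(np.mean(x))

    defs: list[FeatureDef] = []
    if "linear" in spec.classes:
        for var in bounds:
            defs.append(FeatureDef(f"{var}", "linear", (var,)))
    if "quadratic" in spec.classes:
        for var in bounds:
            defs.append(FeatureDef(f"{var}^2", "quadratic", (var,)))
    if "product" in spec.classes:
        items = list(bounds)
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                defs.append(FeatureDef(f"{a}*{b}", "product", (a, b)))
    if "hinge" in spec.classes:
        k = spec.hinge_knots
        qs = np.arange(1, k + 1) / (k + 1)
        for var in bounds:
            lo, hi = bounds[var]
            u = (np.clip(np.asarray(background[var], dtype=float), lo, hi) - lo) / (hi - lo)
            knots = np.unique(np.round(np.quantile(u, qs), 12))
            knots = knots[(knots > 0) & (knots < 1)]
            for t in knots:
                defs.append(FeatureDef(f"{var}'h{t:.4g}", "hinge_forward", (var,), knot=float(t)))
            for t in knots:
                defs.append(FeatureDef(f"{var}`h{t:.4g}", "hinge_reverse", (var,), knot=float(t)))

    categories: dict[str, list[float]] = {}
    if "categorical" in spec.classes:
        for var in categorical:
            obs = set(np.unique(np.asarray(background[var], dtype=float)))
            if presence is not None and var in presence:
                obs |= set(np.unique(np.asarray(presence[var], dtype=float)))
            levels = sorted(obs)
            categories[var] = levels
            vals = np.asarray(background[var], dtype=float)
            lv, ct = np.unique(vals, return_counts=True)
            modes[var] = float(lv[np.argmax(ct)])
            for level in levels:
                defs.append(FeatureDef(f"{var}={level:g}", "categorical", (var,), category=float(level)))

    return FeatureMap(defs, bounds, categories, means, modes)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    feature_map: FeatureMap
    lambdas: np.ndarray
    log_partition: float           # log Σ_b exp(λ·f(b)) over training background
    n_background: int
    entropy: float                 # H of the fitted raw distribution
    gain: float                    # final regularised training gain
    gain_path: list[float]         # per-sweep gain trajectory
    gain_credit: dict[str, float]  # per-variable accumulated gain credit
    beta: np.ndarray
    converged: bool
    n_iterations: int
    spec: FeatureSpec
    seed: int | None = None

    # -- prediction ---------------------------------------------------------
    def raw_scores(self, table: pd.DataFrame) -> np.ndarray:
        f = self.feature_map.transform(table)
        return np.exp(f @ self.lambdas - self.log_partition)

    def logistic_scores(self, table: pd.DataFrame, output: str = "logistic") -> np.ndarray:
        r = self.raw_scores(table)
        re_h = r * np.exp(self.entropy)
        if output == "logistic":
            return re_h / (1.0 + re_h)
        if output == "cloglog":
            return 1.0 - np.exp(-re_h)
        raise ValueError(f"unknown output {output!r}")

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "feature_map": self.feature_map.to_dict(),
            "lambdas": self.lambdas.tolist(),
            "log_partition": self.log_partition,
            "n_background": self.n_background,
            "entropy": self.entropy,
            "gain": self.gain,
            "gain_path": self.gain_path,
            "gain_credit": self.gain_credit,
            "beta": self.beta.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "spec": {"classes": list(self.spec.classes),
                     "hinge_knots": self.spec.hinge_knots, "beta": self.spec.beta},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        p = json.loads(Path(path).read_text())
        return cls(
            feature_map=FeatureMap.from_dict(p["feature_map"]),
            lambdas=np.asarray(p["lambdas"]),
            log_partition=p["log_partition"],
            n_background=p["n_background"],
            entropy=p["entropy"],
            gain=p["gain"],
            gain_path=list(p["gain_path"]),
            gain_credit=dict(p["gain_credit"]),
            beta=np.asarray(p["beta"]),
            converged=p["converged"],
            n_iterations=p["n_iterations"],
            spec=FeatureSpec(tuple(p["spec"]["classes"]), p["spec"]["hinge_knots"],
                             p["spec"]["beta"]),
            seed=p["seed"],
        )


def _soft(z: float, t: float) -> float:
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def fit(presence: pd.DataFrame, background: pd.DataFrame, spec: FeatureSpec,
        max_iterations: int = 5000, tol: float = 1e-5, seed: int | None = None,
        categorical: Sequence[str] = (), feature_map: FeatureMap | None = None
        ) -> MaxentModel:
    """Fit the model by cyclic coordinate descent.

    ``presence``/``background`` are covariate tables.  One "iteration" is a
    single coordinate (feature-weight) update; each update uses a Newton
    soft-threshold step with backtracking, so the regularised gain never
    decreases.  Convergence is declared when a full sweep improves the gain
    by less than ``tol``; exhausting ``max_iterations`` without that sets
    ``converged=False`` (not an error).
    """
    if len(presence) < 2:
        raise ValueError("need at least 2 presence records")
    if feature_map is None:
        feature_map = build_feature_map(background, spec, categorical, presence)
    if feature_map.n_features == 0:
        raise ValueError("feature map is empty (all variables constant?)")
    fp = feature_map.transform(presence)
    fb = feature_map.transform(background)
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fb))):
        raise ValueError("non-finite feature values")
    m = fp.shape[0]
    s = np.maximum(fp.std(axis=0), 1e-3)
    beta = spec.beta * s / np.sqrt(m)

    lam, log_z, gain, gain_path, credit, n_iter, converged = _coordinate_descent(
        fp.mean(axis=0), fb, beta, max_iterations, tol,
        sources=[d.variables for d in feature_map.defs])

    eta = fb @ lam
    p = np.exp(eta - logsumexp(eta))
    entropy = float(-np.sum(p * np.log(np.maximum(p, 1e-300))))
    if not converged:
        log.warning("coordinate descent did not converge in %d iterations", max_iterations)
    return MaxentModel(
        feature_map=feature_map, lambdas=lam, log_partition=float(log_z),
        n_background=fb.shape[0], entropy=entropy, gain=float(gain),
        gain_path=gain_path, gain_credit=credit, beta=beta,
        converged=converged, n_iterations=n_iter, spec=spec, seed=seed,
    )


def _coordinate_descent(pbar: np.ndarray, fb: np.ndarray, beta: np.ndarray,
                        max_iterations: int, tol: float,
                        sources: list[tuple[str, ...]]):
    """Maximise G(λ) = pbar·λ − logZ(λ) + log N − Σβ|λ| coordinate-wise."""
    n, d = fb.shape
    lam = np.zeros(d)
    eta = np.zeros(n)
    log_z = np.log(n)
    log_n = np.log(n)
    gain = 0.0
    gain_path: list[float] = [gain]
    credit: dict[str, float] = {}
    n_iter = 0
    converged = False

    while n_iter < max_iterations and not converged:
        gain_start = gain
        for j in range(d):
            if n_iter >= max_iterations:
                break
            n_iter += 1
            fj = fb[:, j]
            w = np.exp(eta - log_z)
            ef = float(w @ fj)
            var = max(float(w @ (fj * fj)) - ef * ef, 1e-12)
            g = pbar[j] - ef
            new = _soft(lam[j] + g / var, beta[j] / var)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # backtracking: keep the regularised gain non-decreasing
            accepted = False
            for _ in range(50):
                log_z_try = float(logsumexp(eta + delta * fj))
                d_gain = (pbar[j] * delta - (log_z_try - log_z)
                          - beta[j] * (abs(lam[j] + delta) - abs(lam[j])))
                if d_gain >= -1e-12:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-14:
                    break
            if not accepted:
                continue
            eta += delta * fj
            log_z = log_z_try
            lam[j] += delta
            gain += d_gain
            step_credit = max(d_gain, 0.0)
            for v in sources[j]:
                credit[v] = credit.get(v, 0.0) + step_credit / len(sources[j])
        gain_path.append(gain)
        if abs(gain - gain_start) < tol:
            converged = True
    return lam, log_z, gain, gain_path, credit, n_iter, converged


# ---------------------------------------------------------------------------
# Prediction over stacks
# ---------------------------------------------------------------------------

def _scores_grid(model: MaxentModel, stack: LayerStack, kind: str, output: str) -> Grid:
    mask = stack.shared_mask
    table = stack.table(mask)
    if kind == "raw":
        scores = model.raw_scores(table)
    else:
        scores = model.logistic_scores(table, output=output)
    out = np.full(mask.shape, np.nan)
    out[mask] = scores
    return Grid(stack.header, out)


def predict_raw(model: MaxentModel, data: LayerStack | pd.DataFrame):
    """Raw (exponential-family) output; sums to 1 over the training background."""
    if isinstance(data, LayerStack):
        return _scores_grid(model, data, "raw", "logistic")
    return model.raw_scores(data)


def predict_logistic(model: MaxentModel, data: LayerStack | pd.DataFrame,
                     output: str = "logistic"):
    """Suitability in [0,1] (entropy-anchored logistic, or cloglog)."""
    if isinstance(data, LayerStack):
        return _scores_grid(model, data, "logistic", output)
    return model.logistic_scores(data, output=output)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    combined = np.concatenate([sp, sb])
    if np.all(combined == combined[0]):
        warnings.warn("constant scores; AUC defaults to 0.5", stacklevel=2)
        return 0.5
    ranks = rankdata(combined)
    r_p = ranks[: sp.size].sum()
    u = r_p - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def tss(scores_presence: np.ndarray, scores_background: np.ndarray) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity − 1.

    Background points are treated as absences; candidate thresholds are the
    midpoints of consecutive distinct observed scores (plus the extremes).
    Returns (TSS, maximising threshold — the lowest on ties).
    """
    sp = np.sort(np.asarray(scores_presence, dtype=float))
    sb = np.sort(np.asarray(scores_background, dtype=float))
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    allv = np.unique(np.concatenate([sp, sb]))
    if allv.size == 1:
        return 0.0, float(allv[0])
    mids = (allv[:-1] + allv[1:]) / 2.0
    cand = np.concatenate([[allv[0] - 1.0], mids, [allv[-1] + 1.0]])
    # classified presence when score >= threshold
    sens = 1.0 - np.searchsorted(sp, cand, side="left") / sp.size
    spec = np.searchsorted(sb, cand, side="left") / sb.size
    score = sens + spec - 1.0
    order = np.argsort(cand, kind="stable")
    best = order[np.argmax(score[order])]
    best_val = score.max()
    ties = np.flatnonzero(score >= best_val - 1e-15)
    best = ties[np.argmin(cand[ties])]
    return float(score[best]), float(cand[best])


@dataclass
class EvalReport:
    auc_train: float | None = None
    auc_test: float | None = None
    tss: float | None = None
    tss_threshold: float | None = None
    fold_aucs: list[float] = dc_field(default_factory=list)
    auc_mean: float | None = None
    auc_sd: float | None = None


def evaluate(model: MaxentModel, presence_train: pd.DataFrame,
             presence_test: pd.DataFrame | None, background: pd.DataFrame) -> EvalReport:
    """Train/test AUC and TSS against the background sample."""
    sb = model.raw_scores(background)
    rep = EvalReport()
    rep.auc_train = auc(model.raw_scores(presence_train), sb)
    if presence_test is not None and len(presence_test):
        st = model.raw_scores(presence_test)
        rep.auc_test = auc(st, sb)
        rep.tss, rep.tss_threshold = tss(st, sb)
    else:
        rep.tss, rep.tss_threshold = tss(model.raw_scores(presence_train), sb)
    return rep


def spatial_cross_validate(presences: OccurrenceSet | pd.DataFrame, stack: LayerStack,
                           spec: FeatureSpec, k: int = 10, block_cells: int = 10,
                           seed: int | None = None, background_size: int = 10000,
                           max_iterations: int = 5000, tol: float = 1e-5) -> EvalReport:
    """Spatially blocked k-fold cross-validation.

    The grid is tiled into square blocks of ``block_cells``; blocks are
    assigned to folds round-robin in row-major order after a seeded shuffle.
    Each fold fits on out-of-fold presences and background, and scores the
    in-fold presences against the fold-restricted background.
    """
    if isinstance(presences, pd.DataFrame):
        presences = OccurrenceSet(presences)
    if len(presences) < k:
        raise ValueError(f"need at least k={k} presences")
    h = stack.header
    cov = extract_covariates(presences, stack)
    p_tab = cov.table

    nbx = -(-h.ncols // block_cells)
    nby = -(-h.nrows // block_cells)
    block_ids = np.arange(nbx * nby)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(block_ids)
    fold_of_block = np.empty(nbx * nby, dtype=int)
    fold_of_block[shuffled] = np.arange(nbx * nby) % k

    def fold_of(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return fold_of_block[(rows // block_cells) * nbx + (cols // block_cells)]

    p_folds = fold_of(p_tab["row"].to_numpy(), p_tab["col"].to_numpy())

    mask = stack.shared_mask
    b_rows, b_cols = np.nonzero(mask)
    if b_rows.size > background_size:
        pick = rng.choice(b_rows.size, size=background_size, replace=False)
        b_rows, b_cols = b_rows[pick], b_cols[pick]
    b_tab = pd.DataFrame({n: stack.grids[n].values[b_rows, b_cols] for n in stack.names})
    b_folds = fold_of(b_rows, b_cols)

    fold_aucs: list[float] = []
    for i in range(k):
        test_p = p_tab[p_folds == i]
        if len(test_p) == 0:
            warnings.warn(f"fold {i} has no test presences; skipped", stacklevel=2)
            continue
        train_p = p_tab[p_folds != i]
        train_b = b_tab[b_folds != i]
        test_b = b_tab[b_folds == i]
        if len(train_p) < 2 or len(train_b) < 3 or len(test_b) == 0:
            warnings.warn(f"fold {i} is degenerate; skipped", stacklevel=2)
            continue
        model = fit(train_p, train_b, spec, max_iterations=max_iterations, tol=tol,
                    categorical=stack.categorical_names, seed=seed)
        fold_aucs.append(auc(model.raw_scores(test_p), model.raw_scores(test_b)))
    if not fold_aucs:
        raise ValueError("every fold was empty or degenerate")
    return EvalReport(fold_aucs=fold_aucs,
                      auc_mean=float(np.mean(fold_aucs)),
                      auc_sd=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Per-variable share of the gain credited along the fitting path (%)."""
    variables = model.feature_map.variables
    credit = np.array([max(model.gain_credit.get(v, 0.0), 0.0) for v in variables])
    total = credit.sum()
    if total <= 0:
        warnings.warn("zero total gain credit; contributions set uniform", stacklevel=2)
        credit = np.ones(len(variables))
        total = credit.sum()
    return {v: float(100.0 * c / total) for v, c in zip(variables, credit)}


def permutation_importance(model: MaxentModel, presence: pd.DataFrame,
                           background: pd.DataFrame, seed: int | None = None,
                           reps: int = 10) -> dict[str, float]:
    """Mean training-AUC drop after jointly permuting one variable's values
    across presence + background rows, floored at 0 and normalised to 100%."""
    rng = np.random.default_rng(seed)
    variables = model.feature_map.variables
    m = len(presence)
    combined = pd.concat([presence, background], ignore_index=True)
    base = auc(model.raw_scores(presence), model.raw_scores(background))
    drops = {}
    for var in variables:
        ds = []
        for _ in range(reps):
            perm = combined.copy()
            perm[var] = rng.permutation(perm[var].to_numpy())
            scores = model.raw_scores(perm)
            ds.append(base - auc(scores[:m], scores[m:]))
        drops[var] = max(float(np.mean(ds)), 0.0)
    total = sum(drops.values())
    if total <= 0:
        warnings.warn("no permutation produced an AUC drop; importance set uniform",
                      stacklevel=2)
        return {v: 100.0 / len(variables) for v in variables}
    return {v: 100.0 * d / total for v, d in drops.items()}


@dataclass
class JackknifeResult:
    full_gain: float
    with_only: dict[str, float]
    without: dict[str, float]


def jackknife_gains(presence: pd.DataFrame, background: pd.DataFrame, spec: FeatureSpec,
                    seed: int | None = None, categorical: Sequence[str] = (),
                    max_iterations: int = 5000, tol: float = 1e-5) -> JackknifeResult:
    """Refit with only / without each variable; report regularised gains."""
    variables = [c for c in background.columns if c not in ("row", "col")]
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")

    def _gain(names: list[str]) -> float:
        fm = build_feature_map(background, spec, categorical, presence, variables=names)
        if fm.n_features == 0:
            return 0.0
        model = fit(presence, background, spec, max_iterations=max_iterations,
                    tol=tol, seed=seed, feature_map=fm)
        return model.gain

    full = _gain(variables)
    with_only = {v: _gain([v]) for v in variables}
    without = {v: _gain([w for w in variables if w != v]) for v in variables}
    return JackknifeResult(full, with_only, without)


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurve:
    variable: str
    x: np.ndarray
    suitability: np.ndarray
    threshold: float
    optimal_intervals: list[tuple[float, float]]


def response_curve(model: MaxentModel, variable: str, n_points: int = 100,
                   threshold: float = 0.239, output: str = "logistic") -> ResponseCurve:
    """Sweep one variable over its background range, others held at
    background means (categoricals at their mode); the optimal range is the
    union of sweep intervals with suitability >= threshold."""
    fm = model.feature_map
    if variable not in fm.bounds:
        raise KeyError(f"variable {variable!r} is not a continuous model variable")
    lo, hi = fm.bounds[variable]
    x = np.linspace(lo, hi, n_points)
    data = {variable: x}
    for var in fm.bounds:
        if var != variable:
            data[var] = np.full(n_points, fm.background_means[var])
    for var in fm.categories:
        data[var] = np.full(n_points, fm.background_modes[var])
    y = model.logistic_scores(pd.DataFrame(data), output=output)
    above = y >= threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(x[start]), float(x[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(x[start]), float(x[-1])))
    return ResponseCurve(variable, x, y, threshold, intervals)
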