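"""Adaptive Mamdani fuzzy inference.

All fuzzy variables live on the normalized universe [0, 1].  Input variables
carry two sets, low (L) and high (H), built as a complementary trapezoid
pair whose shoulders sit at two anchor points; for the adaptive stage those
anchors are the two fuzzy c-means cluster centers ("normal" vs "seizure")
estimated per feature and channel, so the membership functions follow the
data.  Output variables carry either three sets (L/M/H anchored at
0.3/0.5/0.7) or the same two-level pair.

Inference is Mamdani: rule firing strength is the minimum of the antecedent
memberships, the implication clips the consequent set at the firing
strength, rules aggregate by pointwise maximum, and the crisp output is the
centroid of the aggregated curve (trapezoidal quadrature on a uniform grid).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

LOW, MED, HIGH = "L", "M", "H"


# --------------------------------------------------------------------------
# membership functions and variables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear trapezoid with breakpoints a <= b <= c <= d.

    Rises from 0 at ``a`` to 1 at ``b``, stays 1 on the core [b, c], falls
    back to 0 at ``d``.  A triangle is the b == c case.  Degenerate edges
    (a == b or c == d) are crisp steps.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"breakpoints must be ordered, got {self}")

    @classmethod
    def triangular(cls, a: float, b: float, c: float) -> "MembershipFunction":
        return cls(a, b, b, c)

    @classmethod
    def trapezoidal(cls, a: float, b: float, c: float, d: float) -> "MembershipFunction":
        return cls(a, b, c, d)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            out[rising] = (x[rising] - self.a) / (self.b - self.a)
        core = (x >= self.b) & (x <= self.c)
        out[core] = 1.0
        if self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            out[falling] = (self.d - x[falling]) / (self.d - self.c)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class FuzzyVariable:
    """Named linguistic variable: ordered label -> set mapping on [0, 1]."""

    name: str
    sets: dict[str, MembershipFunction]

    def membership(self, label: str, x):
        return self.sets[label](x)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.sets)


def two_level_variable(name: str, c_low: float, c_high: float) -> FuzzyVariable:
    """Complementary L/H trapezoid pair with shoulders at the two anchors.

    mu_L + mu_H = 1 everywhere: L = trap(0, 0, c_low, c_high),
    H = trap(c_low, c_high, 1, 1).
    """
    if c_low > c_high:
        raise ValueError("anchors must be ordered")
    if c_low == c_high:
        warnings.warn(f"{name}: coincident anchors produce a crisp step at {c_low}")
    return FuzzyVariable(name, {
        LOW: MembershipFunction.trapezoidal(0.0, 0.0, c_low, c_high),
        HIGH: MembershipFunction.trapezoidal(c_low, c_high, 1.0, 1.0),
    })


def three_level_variable(
    name: str, th_l: float = 0.3, th_m: float = 0.5, th_h: float = 0.7
) -> FuzzyVariable:
    """L/M/H output sets anchored at the printed thresholds 0.3/0.5/0.7."""
    return FuzzyVariable(name, {
        LOW: MembershipFunction.trapezoidal(0.0, 0.0, th_l, th_m),
        MED: MembershipFunction.triangular(th_l, th_m, th_h),
        HIGH: MembershipFunction.trapezoidal(th_m, th_h, 1.0, 1.0),
    })


def build_input_mfs(c_low: float, c_high: float, name: str = "input") -> FuzzyVariable:
    """Adaptive input variable from two FCM cluster centers (normal, seizure)."""
    return two_level_variable(name, c_low, c_high)


# --------------------------------------------------------------------------
# normalization and fuzzy c-means
# --------------------------------------------------------------------------

def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); constant input maps to all 0.5 with a warning."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant input to min-max normalization; returning 0.5")
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek's alternating optimization).

    Minimizes ``sum_ij u_ij^m ||x_j - c_i||^2`` subject to memberships
    summing to 1 per point, by alternating the closed-form center and
    membership updates.  With the defaults used in the detector the
    fuzzifier exponent is 2.0 and at most 100 iterations are run.

    Parameters
    ----------
    n_clusters : int, default 2
    m : float, default 2.0
        Fuzzifier exponent, > 1.
    max_iter : int, default 100
    tol : float, default 1e-5
        Stop when the largest membership change falls below this.
    random_state : int or RandomState, optional
        Seeds the random initial membership matrix.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_features), sorted ascending by
        first coordinate (for 1-D data: c_low first).
    membership_ : ndarray (n_samples, n_clusters), rows sum to 1.
    objective_ : float, final objective value.
    objective_trajectory_ : list of float, non-increasing across iterations.
    n_iter_ : int
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, max_iter: int = 100,
                 tol: float = 1e-5, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        zero = d2 <= 1e-300
        u = np.zeros_like(d2)
        if zero.any():
            rows = zero.any(axis=1)
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        ok = ~zero.any(axis=1)
        p = 1.0 / (self.m - 1.0)
        ratio = (d2[ok][:, :, None] / d2[ok][:, None, :]) ** p
        u[ok] = 1.0 / ratio.sum(axis=2)
        return u

    def fit(self, X, y=None):
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        X = check_array(np.asarray(X, dtype=float).reshape(len(X), -1))
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} distinct points, got fewer"
            )
        rng = check_random_state(self.random_state)
        u = rng.random_sample((X.shape[0], self.n_clusters))
        u /= u.sum(axis=1, keepdims=True)
        self.objective_trajectory_ = []
        for it in range(self.max_iter):
            um = u ** self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u_new = self._memberships(X, centers)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
            self.objective_trajectory_.append(float(((u_new ** self.m) * d2).sum()))
            shift = float(np.abs(u_new - u).max())
            u = u_new
            if shift < self.tol:
                break
        order = np.argsort(centers[:, 0])
        self.cluster_centers_ = centers[order]
        self.membership_ = u[:, order]
        self.objective_ = self.objective_trajectory_[-1]
        self.n_iter_ = it + 1
        self.labels_ = np.argmax(self.membership_, axis=1)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(np.asarray(X, dtype=float).reshape(len(X), -1))
        return np.argmax(self._memberships(X, self.cluster_centers_), axis=1)


def fcm(values: np.ndarray, c: int = 2, m: float = 2.0, max_iter: int = 100,
        tol: float = 1e-5, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """1-D convenience wrapper: returns (sorted centers, membership matrix)."""
    est = FuzzyCMeans(n_clusters=c, m=m, max_iter=max_iter, tol=tol,
                      random_state=seed).fit(np.asarray(values, dtype=float)[:, None])
    return est.cluster_centers_[:, 0], est.membership_


# --------------------------------------------------------------------------
# rule bases
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleBase:
    """Exhaustive AND rules: antecedent label tuple -> consequent label."""

    rules: tuple[tuple[tuple[str, ...], str], ...]

    @property
    def n_inputs(self) -> int:
        return len(self.rules[0][0])

    def consequent(self, antecedent: tuple[str, ...]) -> str:
        for ant, cons in self.rules:
            if ant == antecedent:
                return cons
        raise KeyError(antecedent)


def make_rulebase(stage: int) -> RuleBase:
    """The three published rule bases.

    Stage 1 (feature combiner, 16 rules): the fused output is H iff at least
    3 of the 4 feature inputs are H, M iff exactly 2 are H, else L.
    Stage 2 (spatial combiner, 16 rules): H iff at least 2 of the 4 channel
    inputs are H, else L.
    Stage 3 (alarm, 4 rules): (H,H)->H, (H,L)->M, (L,H)->M, (L,L)->L.
    """
    if stage == 1:
        rules = []
        for ant in itertools.product((HIGH, LOW), repeat=4):
            n_high = ant.count(HIGH)
            cons = HIGH if n_high >= 3 else MED if n_high == 2 else LOW
            rules.append((ant, cons))
        return RuleBase(tuple(rules))
    if stage == 2:
        rules = []
        for ant in itertools.product((HIGH, LOW), repeat=4):
            rules.append((ant, HIGH if ant.count(HIGH) >= 2 else LOW))
        return RuleBase(tuple(rules))
    if stage == 3:
        return RuleBase((
            ((HIGH, HIGH), HIGH),
            ((HIGH, LOW), MED),
            ((LOW, HIGH), MED),
            ((LOW, LOW), LOW),
        ))
    raise ValueError(f"unknown stage {stage}; expected 1, 2 or 3")


# --------------------------------------------------------------------------
# inference and defuzzification
# --------------------------------------------------------------------------

def output_grid(grid_n: int = 1001) -> np.ndarray:
    return np.linspace(0.0, 1.0, grid_n)


def _clamp_inputs(values: np.ndarray) -> np.ndarray:
    if np.any((values < 0) | (values > 1)):
        warnings.warn("fuzzy input outside [0, 1]; clamping")
        values = np.clip(values, 0.0, 1.0)
    return values


def mamdani_infer(
    rulebase: RuleBase,
    inputs,
    input_vars: list[FuzzyVariable],
    output_var: FuzzyVariable,
    grid_n: int = 1001,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated output membership curve for one crisp input vector.

    Returns ``(grid, curve)`` where curve[k] = max over rules of
    min(firing strength, consequent membership at grid[k]).
    """
    x = _clamp_inputs(np.asarray(inputs, dtype=float))
    if x.shape != (rulebase.n_inputs,):
        raise ValueError(f"expected {rulebase.n_inputs} inputs, got {x.shape}")
    grid = output_grid(grid_n)
    curve = np.zeros(grid_n)
    for ant, cons in rulebase.rules:
        firing = min(var.membership(label, xi) for xi, var, label in zip(x, input_vars, ant))
        if firing > 0:
            curve = np.maximum(curve, np.minimum(firing, output_var.membership(cons, grid)))
    return grid, curve


def mamdani_defuzz_batch(
    rulebase: RuleBase,
    X: np.ndarray,
    input_vars: list[FuzzyVariable],
    output_var: FuzzyVariable,
    grid_n: int = 1001,
) -> np.ndarray:
    """Vectorized inference + centroid over rows of X (n_samples, n_inputs)."""
    X = _clamp_inputs(np.asarray(X, dtype=float))
    n = X.shape[0]
    grid = output_grid(grid_n)
    cons_curves = {label: output_var.membership(label, grid) for label in output_var.labels}
    memb = np.stack(
        [np.stack([var.membership(label, X[:, j]) for label in (LOW, MED, HIGH)
                   if label in var.labels], axis=0)
         for j, var in enumerate(input_vars)], axis=0
    )  # (n_inputs, n_labels_per_var, n)  -- label order follows var.labels
    label_index = [
        {label: k for k, label in enumerate(var.labels)} for var in input_vars
    ]
    agg = np.zeros((n, grid_n))
    for ant, cons in rulebase.rules:
        firing = np.ones(n)
        for j, label in enumerate(ant):
            firing = np.minimum(firing, memb[j][label_index[j][label]])
        np.maximum(agg, np.minimum(firing[:, None], cons_curves[cons][None, :]), out=agg)
    return centroid_batch(agg, grid)


def defuzz_centroid(curve: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Centroid of a membership curve by trapezoidal quadrature."""
    curve = np.asarray(curve, dtype=float)
    if grid is None:
        grid = output_grid(len(curve))
    area = np.trapezoid(curve, grid)
    if area <= 0:
        warnings.warn("zero-area membership curve; centroid undefined, returning 0.5")
        return 0.5
    return float(np.trapezoid(grid * curve, grid) / area)


def centroid_batch(curves: np.ndarray, grid: np.ndarray) -> np.ndarray:
    areas = np.trapezoid(curves, grid, axis=1)
    num = np.trapezoid(curves * grid[None, :], grid, axis=1)
    out = np.full(len(curves), 0.5)
    ok = areas > 0
    if not ok.all():
        warnings.warn("zero-area membership curve; centroid undefined, returning 0.5")
    out[ok] = num[ok] / areas[ok]
    return out
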