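"""Weighted l1-regularized logistic regression and stability selection.

The solver minimizes

    sum_j log(1 + exp(-y_j (x^T f_j + c))) + lam * sum_i penalty_i * |x_i|

with an unpenalized intercept ``c`` and labels recoded internally to +/-1
(1 -> +1).  ``penalty_i`` defaults to 1; passing per-feature values solves
the adaptive-penalty form directly, where a feature with weight ``W_i``
receives penalty ``1/W_i``.  Multiplying feature columns by their weights and
solving the uniform-penalty problem is equivalent: if ``x~`` solves the
weighted-column problem, then ``z_i = W_i * x~_i`` solves the adaptive one.

Stability selection re-fits the solver across class-stratified bootstrap
resamples and a descending lambda grid; features selected in strictly more
than half of the runs survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionError",
    "SparseSolution",
    "StabilityProfile",
    "fit_l1_logistic",
    "lambda_max",
    "lambda_grid",
    "stability_select",
]

SUPPORT_TOL = 1e-9  # hard-zero threshold: floating noise must not select


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SparseSolution:
    """Solution of one l1-logistic fit."""

    x: np.ndarray
    intercept: float
    lam: float
    objective: float
    converged: bool
    n_iter: int

    @property
    def support(self) -> np.ndarray:
        """Indices of features with |x_i| above the hard-zero threshold."""
        return np.flatnonzero(np.abs(self.x) > SUPPORT_TOL)


@dataclass(frozen=True)
class StabilityProfile:
    """Per-feature selection frequencies over bootstrap runs."""

    frequencies: pd.Series        # index: feature ids, values in [0, 1]
    grid: np.ndarray
    n_bootstraps: int
    threshold: float

    @property
    def selected(self) -> list:
        """Features with frequency strictly above the threshold."""
        freq = self.frequencies
        return list(freq.index[freq > self.threshold])


def _objective(X: np.ndarray, s: np.ndarray, x: np.ndarray, c: float,
               lam: float, penalty: np.ndarray) -> float:
    z = s * (X @ x + c)
    return float(np.logaddexp(0.0, -z).sum() + lam * (penalty * np.abs(x)).sum())


def _lipschitz(X: np.ndarray) -> float:
    m = X.shape[0]
    A = np.hstack([X, np.ones((m, 1))])
    # ||A||_2^2 / 4 bounds the logistic-loss Hessian over (x, c)
    sigma = np.linalg.norm(A, 2)
    return 0.25 * sigma * sigma


def fit_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float, *,
                    penalty: np.ndarray | None = None,
                    tol: float = 1e-8, max_iter: int = 10000,
                    x0: np.ndarray | None = None, c0: float | None = None,
                    L: float | None = None) -> SparseSolution:
    """FISTA with soft-thresholding for l1-penalized logistic regression.

    Deterministic: fixed step 1/L with L from the exact operator norm of
    [X, 1]; convergence when the relative objective change drops below
    ``tol``.  ``x0``/``c0`` warm-start path fits; ``L`` may be precomputed
    once per matrix and reused along a lambda path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise SelectionError("non-finite values in feature matrix")
    if lam < 0:
        raise SelectionError("lambda must be non-negative")
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1} or len(classes) < 2:
        raise SelectionError("labels must contain both classes 0 and 1")
    m, p = X.shape
    s = np.where(y == 1, 1.0, -1.0)
    pen = np.ones(p) if penalty is None else np.asarray(penalty, dtype=float)
    if pen.shape != (p,) or (pen < 0).any():
        raise SelectionError("penalty must be a non-negative p-vector")

    if L is None:
        L = _lipschitz(X)
    step = 1.0 / L

    x = np.zeros(p) if x0 is None else np.array(x0, dtype=float)
    c = float(np.log((y == 1).sum() / (y == 0).sum())) if c0 is None else float(c0)
    vx, vc = x.copy(), c          # FISTA momentum point
    t_k = 1.0
    obj = _objective(X, s, x, c, lam, pen)
    thresh = step * lam * pen

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = s * (X @ vx + vc)
        with np.errstate(over="ignore"):
            mu = s / (1.0 + np.exp(z))        # = s * sigmoid(-z)
        gx = -(X.T @ mu)
        gc = -mu.sum()
        x_new = vx - step * gx
        x_new = np.sign(x_new) * np.maximum(np.abs(x_new) - thresh, 0.0)
        c_new = vc - step * gc

        obj_new = _objective(X, s, x_new, c_new, lam, pen)
        if obj_new > obj:                     # momentum overshoot: restart
            vx, vc, t_k = x.copy(), c, 1.0
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        beta = (t_k - 1.0) / t_next
        vx = x_new + beta * (x_new - x)
        vc = c_new + beta * (c_new - c)
        t_k = t_next

        delta = obj - obj_new
        x, c = x_new, c_new
        obj = obj_new
        if delta <= tol * max(1.0, abs(obj)):
            converged = True
            break

    return SparseSolution(x=x, intercept=c, lam=lam, objective=obj,
                          converged=converged, n_iter=it)


def lambda_max(X: np.ndarray, y: np.ndarray,
               penalty: np.ndarray | None = None) -> float:
    """Smallest lambda at which the all-zero solution is optimal.

    At x = 0 the optimal intercept gives predicted probability pi = n+/m, so
    by the KKT conditions the support stays empty iff
    ``|sum_j f_ij (y_j - pi)| <= lam * penalty_i`` for every feature.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pi = (y == 1).mean()
    grad = X.T @ (np.where(y == 1, 1.0, 0.0) - pi)
    pen = np.ones(X.shape[1]) if penalty is None else np.asarray(penalty, float)
    with np.errstate(divide="ignore"):
        vals = np.abs(grad) / pen
    vals[~np.isfinite(vals)] = 0.0  # infinite penalty: feature never enters
    lm = float(vals.max())
    if lm <= 0:
        raise SelectionError("degenerate matrix: lambda_max is zero")
    return lm


def lambda_grid(X: np.ndarray, y: np.ndarray, n_values: int = 10,
                ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending grid from lambda_max to ratio * lambda_max."""
    if n_values < 1 or not (0 < ratio < 1):
        raise SelectionError("need n_values >= 1 and 0 < ratio < 1")
    lm = lambda_max(X, y)
    if n_values == 1:
        return np.array([lm])
    return np.geomspace(lm, ratio * lm, n_values)


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    take_pos = rng.choice(idx_pos, size=len(idx_pos), replace=True)
    take_neg = rng.choice(idx_neg, size=len(idx_neg), replace=True)
    return np.concatenate([take_pos, take_neg])


def stability_select(X: np.ndarray, y: np.ndarray, grid: np.ndarray, *,
                     n_bootstraps: int = 100, threshold: float = 0.5,
                     seed: int | np.random.SeedSequence = 0,
                     min_lambda_hits: int = 1,
                     feature_ids=None,
                     tol: float = 1e-7, max_iter: int = 5000,
                     max_retries: int = 20) -> StabilityProfile:
    """Selection frequencies over stratified bootstrap resamples.

    Each bootstrap draws, with replacement and stratified by class, a resample
    of the original size and fits the solver along the descending ``grid``
    with warm starts.  A feature counts as selected in that run when its
    coefficient is nonzero at >= ``min_lambda_hits`` grid points.  The
    selected set keeps features whose frequency is strictly above
    ``threshold``.  Bit-reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(np.unique(y).tolist())) < 2:
        raise SelectionError("labels must contain both classes")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise SelectionError("lambda grid must be descending")
    m, p = X.shape
    if feature_ids is None:
        feature_ids = list(range(p))

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    counts = np.zeros(p)
    for _ in range(n_bootstraps):
        idx = _stratified_bootstrap(y, rng)
        retries = 0
        while len(set(np.unique(y[idx]).tolist())) < 2:
            # unreachable under stratification, kept as a guard
            retries += 1
            if retries > max_retries:
                raise SelectionError("bootstrap kept drawing a single class")
            idx = _stratified_bootstrap(y, rng)
        Xb, yb = X[idx], y[idx]
        L = _lipschitz(Xb)
        hits = np.zeros(p, dtype=int)
        sol_x, sol_c = None, None
        for lam in grid:
            sol = fit_l1_logistic(Xb, yb, lam, tol=tol, max_iter=max_iter,
                                  x0=sol_x, c0=sol_c, L=L)
            sol_x, sol_c = sol.x, sol.intercept
            hits[np.abs(sol.x) > SUPPORT_TOL] += 1
        counts += hits >= min_lambda_hits

    freq = pd.Series(counts / n_bootstraps, index=feature_ids, name="frequency")
    return StabilityProfile(frequencies=freq, grid=grid,
                            n_bootstraps=n_bootstraps, threshold=threshold)
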