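"""Elastic-net penalized logistic regression along a warm-started λ path.

Minimises, over intercept b0 and coefficients w,

    (1/n) Σ_i log(1 + exp(-y*_i (b0 + x_i·w)))  +  λ [ (1−α)/2 ‖w‖² + α ‖w‖₁ ]

with features standardised internally to mean 0 / sd 1 (the penalty applies
on that scale; returned coefficients are back-transformed to the original
scale).  The path starts at λ_max, the smallest λ at which every coefficient
is zero, and proceeds by warm starts.  Fitting is IRLS with cyclic
coordinate descent and an active-set strategy (full-gradient screening
between active-set convergences); ridge (α = 0) uses a direct linear solve
inside IRLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_WMIN = 1e-5   # floor on IRLS weights, as in glmnet
_ALPHA_FLOOR = 1e-3  # surrogate for λ_max when α → 0


@dataclass
class EnetPath:
    """Coefficient path of a penalized logistic fit.

    ``coefs`` is features × λ on the original input scale; ``coefs_std`` on
    the internal standardized scale (needed for optimality diagnostics).
    """

    alpha: float
    lambdas: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray
    coefs_std: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=0)

    def predict_linear(self, X: np.ndarray, j: int) -> np.ndarray:
        return self.intercepts[j] + X @ self.coefs[:, j]


def lambda_max(Xs: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest λ with an all-zero solution (standardized X)."""
    n = len(y)
    g = np.abs(Xs.T @ (y - y.mean())) / n
    return float(g.max() / max(alpha, _ALPHA_FLOOR))


def default_lambdas(Xs, y, alpha, n_lambda=50, lambda_min_ratio=None):
    n, p = Xs.shape
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if n > p else 1e-2
    lmax = lambda_max(Xs, y, alpha)
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


try:  # compiled coordinate sweeps; pure-python fallback keeps results identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _cd_sweeps(Xs, v, b0, w, r, active, thr, denom, vx2, n, vsum, tol, max_sweeps):
    """Cyclic coordinate descent over ``active``; mutates w and r in place."""
    for _ in range(max_sweeps):
        delta = 0.0
        num = 0.0
        for i in range(r.shape[0]):
            num += v[i] * r[i]
        b0_new = b0 + num / vsum
        d = b0_new - b0
        if abs(d) > delta:
            delta = abs(d)
        for i in range(r.shape[0]):
            r[i] -= d
        b0 = b0_new
        for jj in range(active.shape[0]):
            j = active[jj]
            rho = 0.0
            for i in range(r.shape[0]):
                rho += v[i] * Xs[i, j] * r[i]
            rho = rho / n + vx2[j] * w[j]
            if rho > thr:
                wn = (rho - thr) / denom[j]
            elif rho < -thr:
                wn = (rho + thr) / denom[j]
            else:
                wn = 0.0
            if wn != w[j]:
                dw = w[j] - wn
                for i in range(r.shape[0]):
                    r[i] += Xs[i, j] * dw
                if abs(dw) > delta:
                    delta = abs(dw)
                w[j] = wn
        if delta < tol:
            break
    return b0


def _cd_fixed_weights(Xs, z, v, b0, w, lam, alpha, active, tol, max_sweeps=1000):
    """Coordinate descent on the weighted least-squares surrogate.

    Maintains the residual r = z − b0 − Xs·w; sweeps the active set until
    stable, then screens all coordinates with one full-gradient pass and
    repeats if violations enter.
    """
    n = len(z)
    vx2 = (v @ (Xs**2)) / n  # denominator terms, fixed for these weights
    vsum = v.sum()
    r = z - b0 - Xs @ w
    thr = lam * alpha
    denom = vx2 + lam * (1.0 - alpha)
    while True:
        act = np.fromiter(active, dtype=np.int64, count=len(active))
        act.sort()
        b0 = _cd_sweeps(Xs, v, b0, w, r, act, thr, denom, vx2,
                        float(n), vsum, tol, max_sweeps)
        # screen every coordinate for KKT violations on the surrogate
        rho_all = (Xs.T @ (v * r)) / n + vx2 * w
        wnew_all = np.sign(rho_all) * np.maximum(np.abs(rho_all) - thr, 0.0) / denom
        viol = np.flatnonzero(np.abs(wnew_all - w) > tol)
        new = [j for j in viol if j not in active]
        if not new:
            return b0, w
        active |= set(new)


def _ridge_fixed_weights(Xs, z, v, lam):
    n, p = Xs.shape
    Xa = np.column_stack([np.ones(n), Xs])
    A = (Xa.T * v) @ Xa / n
    A[1:, 1:] += lam * np.eye(p)
    b = (Xa.T @ (v * z)) / n
    sol = np.linalg.solve(A, b)
    return sol[0], sol[1:]


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-9,
    max_irls: int = 100,
) -> EnetPath:
    """Fit the warm-started elastic-net logistic path.

    Parameters
    ----------
    X, y
        Raw (unstandardized) design and 0/1 outcomes.
    alpha
        Elastic-net mixing in [0, 1]: 1 = lasso, 0 = ridge.
    lambdas
        Penalty sequence (descending); computed from the data when omitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd <= 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) dropped", stacklevel=2)
    sd_safe = np.where(const, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, const] = 0.0

    if lambdas is None:
        lambdas = default_lambdas(Xs, y, alpha, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be non-increasing")

    ybar = y.mean()
    if not 0.0 < ybar < 1.0:
        raise ValueError("outcome is constant")
    b0 = float(np.log(ybar / (1.0 - ybar)))
    w = np.zeros(p)
    intercepts = np.empty(len(lambdas))
    coefs_std = np.empty((p, len(lambdas)))
    active: set[int] = set()
    for li, lam in enumerate(lambdas):
        for _ in range(max_irls):
            eta = np.clip(b0 + Xs @ w, -30.0, 30.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            v = np.maximum(mu * (1.0 - mu), _WMIN)
            z = eta + (y - mu) / v
            b0_old, w_old = b0, w.copy()
            if alpha == 0.0:
                b0, w = _ridge_fixed_weights(Xs, z, v, lam)
                w[const] = 0.0
            else:
                b0, w = _cd_fixed_weights(Xs, z, v, b0, w, lam, alpha, active, tol)
            if max(abs(b0 - b0_old), float(np.max(np.abs(w - w_old), initial=0.0))) < tol * 10:
                break
        active = set(np.flatnonzero(w))
        intercepts[li] = b0
        coefs_std[:, li] = w
    coefs = coefs_std / sd_safe[:, None]
    coefs[const] = 0.0
    intercepts_orig = intercepts - mean @ coefs
    return EnetPath(
        alpha=alpha,
        lambdas=lambdas,
        intercepts=intercepts_orig,
        coefs=coefs,
        coefs_std=coefs_std,
        x_mean=mean,
        x_sd=sd_safe,
    )


def kkt_violation(path: EnetPath, X: np.ndarray, y: np.ndarray, j: int) -> float:
    """Worst violation of the stationarity conditions at path point ``j``.

    On the standardized scale the subgradient conditions are
    |g_k| ≤ λα for w_k = 0 and g_k = −λα·sign(w_k) otherwise, where
    g_k = (1/n) Σ_i x_ik (μ_i − y_i) + λ(1−α) w_k.
    """
    Xs = (np.asarray(X, float) - path.x_mean) / path.x_sd
    lam, alpha = path.lambdas[j], path.alpha
    w = path.coefs_std[:, j]
    eta = path.intercepts[j] + np.asarray(X, float) @ path.coefs[:, j]
    mu = 1.0 / (1.0 + np.exp(-eta))
    g = Xs.T @ (mu - y) / len(y) + lam * (1.0 - alpha) * w
    zero = w == 0
    viol_zero = np.maximum(np.abs(g[zero]) - lam * alpha, 0.0)
    viol_nz = np.abs(g[~zero] + lam * alpha * np.sign(w[~zero]))
    out = 0.0
    if viol_zero.size:
        out = max(out, float(viol_zero.max()))
    if viol_nz.size:
        out = max(out, float(viol_nz.max()))
    # intercept is unpenalized: its gradient must vanish
    out = max(out, abs(float(np.mean(mu - y))))
    return out
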