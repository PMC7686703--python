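"""Firth bias-reduced logistic regression with profile-penalized CIs.

`FirthLogit` maximises the Jeffreys-penalized log-likelihood

    l*(θ) = l(θ) + ½ log det I(θ),

where I is the Fisher information, by Newton iterations on the modified
score U*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij (h_i: hat-matrix
diagonal), with step-halving.  Estimates stay finite under complete
separation and zero cells.  Confidence intervals come from the profile
penalized likelihood (χ²₁ cutoff) found by bisection, and p-values from the
penalized likelihood-ratio test, matching the conventions of bias-reduction
logistic software.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _penalized_loglik(X, y, theta):
    eta = np.clip(X @ theta, -30.0, 30.0)
    pi = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ np.log(pi) + (1 - y) @ np.log1p(-pi))
    W = pi * (1.0 - pi)
    info = (X.T * W) @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(X, y, theta0=None, fixed: dict[int, float] | None = None,
                  max_iter=100, tol=1e-10):
    """Maximise the penalized likelihood; coordinates in ``fixed`` are held."""
    n, p = X.shape
    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed])
    theta = np.zeros(p) if theta0 is None else theta0.copy()
    for j, v in fixed.items():
        theta[j] = v
    ll = _penalized_loglik(X, y, theta)
    for _ in range(max_iter):
        eta = np.clip(X @ theta, -30.0, 30.0)
        pi = 1.0 / (1.0 + np.exp(-eta))
        W = pi * (1.0 - pi)
        XW = X * W[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Fisher information") from exc
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - pi + h * (0.5 - pi))
        if len(free) == 0:
            break
        sub_info = info[np.ix_(free, free)]
        try:
            step_free = np.linalg.solve(sub_info, score[free])
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Fisher information") from exc
        # step-halving on the penalized likelihood
        scale = 1.0
        for _ in range(30):
            cand = theta.copy()
            cand[free] += scale * step_free
            ll_new = _penalized_loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        theta, ll = cand, ll_new
        if np.max(np.abs(scale * step_free)) < tol:
            return theta, ll, True
    grad_norm = float(np.max(np.abs(score[free]))) if len(free) else 0.0
    if len(free) and grad_norm > 1e-4:
        raise ValueError(
            f"Firth fit did not converge (max |score| = {grad_norm:.3g})"
        )
    return theta, ll, True


class FirthLogit:
    """Bias-reduced logistic model: outcome y on covariate matrix X.

    An intercept column is added unless ``add_intercept=False``.
    """

    def __init__(self, y, X, names: list[str] | None = None, add_intercept=True):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("outcome is constant")
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + list(names)
        self.y, self.X, self.names = y, X, list(names)

    def fit(self, ci_level: float = 0.95) -> "FirthLogitResults":
        theta, ll, _ = _firth_newton(self.X, self.y)
        cut = stats.chi2.ppf(ci_level, 1)
        rows = []
        for j, name in enumerate(self.names):
            lo, hi = self._profile_ci(j, theta, ll, cut)
            theta0, ll0, _ = _firth_newton(self.X, self.y, theta0=theta, fixed={j: 0.0})
            lrt = max(2.0 * (ll - ll0), 0.0)
            pval = float(stats.chi2.sf(lrt, 1))
            rows.append((name, theta[j], np.exp(theta[j]), np.exp(lo), np.exp(hi), pval))
        table = pd.DataFrame(
            rows, columns=["term", "estimate", "OR", "ci_low", "ci_high", "p"]
        ).set_index("term")
        return FirthLogitResults(self, theta, ll, table, ci_level)

    def _profile_ci(self, j, theta_hat, ll_hat, cut, tol=1e-6):
        """Bisection on the penalized LRT statistic for coefficient j."""
        target = ll_hat - cut / 2.0

        def profile(val):
            th, ll, _ = _firth_newton(self.X, self.y, theta0=theta_hat, fixed={j: val})
            return ll

        bounds = []
        for direction in (-1.0, 1.0):
            step = 0.5
            lo_val, hi_val = theta_hat[j], theta_hat[j]
            ll_cur = ll_hat
            for _ in range(60):
                hi_val = lo_val + direction * step
                ll_cur = profile(hi_val)
                if ll_cur < target:
                    break
                lo_val = hi_val
                step *= 2.0
            else:
                bounds.append(direction * np.inf)
                continue
            a, b = lo_val, hi_val  # profile(a) >= target > profile(b)
            while abs(b - a) > tol:
                mid = 0.5 * (a + b)
                if profile(mid) >= target:
                    a = mid
                else:
                    b = mid
            bounds.append(0.5 * (a + b))
        lo = min(bounds)
        hi = max(bounds)
        return lo, hi


class FirthLogitResults:
    def __init__(self, model, params, penalized_llf, table, ci_level):
        self.model = model
        self.params = pd.Series(params, index=model.names)
        self.penalized_llf = penalized_llf
        self.table = table
        self.ci_level = ci_level

    def summary(self) -> str:
        lines = [
            "Firth bias-reduced logistic regression",
            f"n = {len(self.model.y)}, penalized log-likelihood = {self.penalized_llf:.4f}",
            "",
            self.table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
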