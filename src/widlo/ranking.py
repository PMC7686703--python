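"""Per-CpG ranking statistics and geometric-mean rank aggregation.

Five statistics rank CpGs for their association with the L/O community
type, each sensitive to a different facet of the signal:

- ``adjusted_logistic`` — per-probe logistic regression of the label on
  beta, adjusted for age and immune cell proportion (IC); Wald test.
- ``welch`` — unequal-variance two-sample t-test on beta between groups.
- ``bartlett`` — differential variability between groups.
- ``delta_beta`` — difference of the IC→0 extrapolated group intercepts of
  within-group linear fits of beta on IC (an estimate of the pure-epithelial
  group difference); ranked by magnitude.
- ``celldmc`` — cell-type interaction model: beta regressed on compartment
  fractions and fraction × label interactions, testing in which compartment
  the label effect acts.

The aggregated ranking orders probes by the geometric mean of their five
per-method ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

METHODS = ("adjusted_logistic", "welch", "bartlett", "delta_beta", "celldmc")

HYPER, HYPO = "hyper_in_O", "hypo_in_O"


def _as_binary(labels: pd.Series) -> np.ndarray:
    """Encode O = 1, L = 0 (a higher index favours O-type)."""
    arr = np.asarray(labels)
    bad = ~np.isin(arr, ("L", "O"))
    if bad.any():
        raise ValueError(f"labels must be 'L'/'O'; got {set(arr[bad])}")
    return (arr == "O").astype(float)


def _assign_ranks(df: pd.DataFrame, key: np.ndarray) -> pd.DataFrame:
    """Rank 1..n ascending in ``key``, ties broken by probe id (stable)."""
    order = np.lexsort((df.index.to_numpy(), key))
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _batched_logistic_wald(B: np.ndarray, covars: np.ndarray, y: np.ndarray,
                           max_iter: int = 50, tol: float = 1e-8,
                           block: int = 512):
    """Wald z for the beta coefficient of logit(y) ~ beta_j + covariates.

    ``B`` is probes × samples; ``covars`` is samples × c (age, IC, ...).
    Newton–Raphson run simultaneously over blocks of probes.  Returns
    (coef, z, converged) arrays over probes.
    """
    n_probes, n = B.shape
    k = 2 + covars.shape[1]  # intercept + beta + covariates
    coef = np.zeros(n_probes)
    zval = np.zeros(n_probes)
    conv = np.zeros(n_probes, dtype=bool)
    base = np.column_stack([np.ones(n), np.zeros(n), covars])
    for start in range(0, n_probes, block):
        sl = slice(start, min(start + block, n_probes))
        m = sl.stop - sl.start
        X = np.broadcast_to(base, (m, n, k)).copy()
        X[:, :, 1] = B[sl]
        W = np.zeros((m, k))
        W[:, 0] = np.log(y.mean() / (1 - y.mean()))
        ok = np.ones(m, dtype=bool)
        done = np.zeros(m, dtype=bool)
        H = np.zeros((m, k, k))
        for _ in range(max_iter):
            eta = np.clip(np.einsum("mnk,mk->mn", X, W), -30.0, 30.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = np.einsum("mnk,mn->mk", X, y[None, :] - mu)
            w = mu * (1.0 - mu)
            H = np.einsum("mnk,mn,mnl->mkl", X, w, X)
            H[:, np.arange(k), np.arange(k)] += 1e-10
            try:
                step = np.linalg.solve(H, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.zeros_like(g)
                for i in range(m):
                    try:
                        step[i] = np.linalg.solve(H[i], g[i])
                    except np.linalg.LinAlgError:
                        ok[i] = False
            step = np.where(np.isfinite(step), step, 0.0)
            W = W + step
            done = np.max(np.abs(step), axis=1) < tol
            if done.all():
                break
        ok &= done & np.isfinite(W).all(axis=1) & (np.abs(W[:, 1]) < 1e3)
        se = np.full(m, np.nan)
        try:
            Hinv = np.linalg.inv(H)
            var = Hinv[:, 1, 1]
            good = var > 0
            se[good] = np.sqrt(var[good])
        except np.linalg.LinAlgError:
            ok[:] = False
        ok &= np.isfinite(se) & (se > 0)
        coef[sl] = np.where(ok, W[:, 1], 0.0)
        zval[sl] = np.where(ok, W[:, 1] / np.where(ok, se, 1.0), 0.0)
        conv[sl] = ok
    return coef, zval, conv


def rank_adjusted_logistic(
    beta: pd.DataFrame, labels: pd.Series, age: pd.Series, ic: pd.Series
) -> pd.DataFrame:
    """Age- and IC-adjusted per-probe logistic Wald ranking with BH q-values."""
    y = _as_binary(labels.loc[beta.columns])
    n1 = int(y.sum())
    if min(n1, len(y) - n1) < 10:
        raise ValueError("need >= 10 samples per community type")
    covars = np.column_stack([
        np.asarray(age.loc[beta.columns], dtype=float),
        np.asarray(ic.loc[beta.columns], dtype=float),
    ])
    B = beta.to_numpy(dtype=float)
    if np.isnan(B).any():
        raise ValueError("beta matrix contains missing values; impute first")
    # constant probes are inestimable: flag without entering the Newton scan
    variable = B.std(axis=1) > 0
    coef = np.zeros(B.shape[0])
    z = np.zeros(B.shape[0])
    conv = np.zeros(B.shape[0], dtype=bool)
    if variable.any():
        c, zz, ok = _batched_logistic_wald(B[variable], covars, y)
        coef[variable], z[variable], conv[variable] = c, zz, ok
    p = np.where(conv, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    stat = np.where(conv, z, 0.0)
    out = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "q": fdr_adjust(p),
            "direction": np.where(coef > 0, HYPER, HYPO),
            "flagged": ~conv,
        },
        index=beta.index,
    )
    out = _assign_ranks(out, p)
    out.attrs["method"] = "adjusted_logistic"
    return out


def rank_welch(beta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-probe Welch unequal-variance t-test between O and L."""
    y = _as_binary(labels.loc[beta.columns]).astype(bool)
    B = beta.to_numpy(dtype=float)
    BO, BL = B[:, y], B[:, ~y]
    nO, nL = BO.shape[1], BL.shape[1]
    mO, mL = BO.mean(axis=1), BL.mean(axis=1)
    vO, vL = BO.var(axis=1, ddof=1), BL.var(axis=1, ddof=1)
    denom = vO / nO + vL / nL
    zero = denom <= 1e-18  # constant in both groups (up to float summation)
    t = np.where(zero, 0.0, (mO - mL) / np.sqrt(np.where(zero, 1.0, denom)))
    with np.errstate(divide="ignore", invalid="ignore"):
        df = denom**2 / ((vO / nO) ** 2 / (nO - 1) + (vL / nL) ** 2 / (nL - 1))
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), np.where(zero, 1.0, df)))
    out = pd.DataFrame(
        {
            "statistic": t,
            "p": p,
            "direction": np.where(mO - mL > 0, HYPER, HYPO),
            "flagged": zero,
        },
        index=beta.index,
    )
    out = _assign_ranks(out, p)
    out.attrs["method"] = "welch"
    return out


def rank_bartlett(beta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-probe Bartlett test of equal variances between O and L."""
    y = _as_binary(labels.loc[beta.columns]).astype(bool)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("Bartlett test needs >= 2 samples per group")
    B = beta.to_numpy(dtype=float)
    BO, BL = B[:, y], B[:, ~y]
    nO, nL = BO.shape[1], BL.shape[1]
    vO, vL = BO.var(axis=1, ddof=1), BL.var(axis=1, ddof=1)
    N, kg = nO + nL, 2
    sp2 = ((nO - 1) * vO + (nL - 1) * vL) / (N - kg)
    zero = (vO <= 1e-18) | (vL <= 1e-18)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (N - kg) * np.log(sp2) - ((nO - 1) * np.log(vO) + (nL - 1) * np.log(vL))
    C = 1.0 + (1.0 / (nO - 1) + 1.0 / (nL - 1) - 1.0 / (N - kg)) / (3.0 * (kg - 1))
    stat = np.where(zero, 0.0, T / C)
    p = np.where(zero, 1.0, stats.chi2.sf(np.where(zero, 0.0, stat), kg - 1))
    out = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "direction": np.where(vO > vL, HYPER, HYPO),
            "flagged": zero,
        },
        index=beta.index,
    )
    out = _assign_ranks(out, p)
    out.attrs["method"] = "bartlett"
    return out


def rank_delta_beta(
    beta: pd.DataFrame, labels: pd.Series, ic: pd.Series
) -> pd.DataFrame:
    """Δβ: difference of the IC = 0 intercepts of within-group OLS fits.

    For each probe, beta is regressed on IC separately in the O and in the L
    group; Δβ = intercept_O − intercept_L extrapolates the group difference
    to a sample free of immune cells.  Probes are ranked by descending |Δβ|.
    """
    y = _as_binary(labels.loc[beta.columns]).astype(bool)
    icv = np.asarray(ic.loc[beta.columns], dtype=float)
    B = beta.to_numpy(dtype=float)
    intercepts = {}
    for name, mask in (("O", y), ("L", ~y)):
        x = icv[mask]
        if mask.sum() < 2 or np.ptp(x) <= 0:
            raise ValueError(
                f"group {name}: need >= 2 samples with non-identical IC "
                "(intercept at IC=0 unidentifiable)"
            )
        X = np.column_stack([np.ones(mask.sum()), x])
        coefs = np.linalg.pinv(X) @ B[:, mask].T  # 2 × probes
        intercepts[name] = coefs[0]
    delta = intercepts["O"] - intercepts["L"]
    out = pd.DataFrame(
        {
            "statistic": delta,
            "direction": np.where(delta > 0, HYPER, HYPO),
            "flagged": False,
        },
        index=beta.index,
    )
    out = _assign_ranks(out, -np.abs(delta))
    out.attrs["method"] = "delta_beta"
    return out


def rank_celldmc(
    beta: pd.DataFrame, labels: pd.Series, fractions: pd.DataFrame,
    compartments: tuple[str, ...] = ("epithelial", "fibroblast", "immune"),
) -> pd.DataFrame:
    """Cell-type interaction model for compartment-resolved label effects.

    Fits, per probe, beta ~ Σ_k f_k + Σ_k f_k × label (no global intercept)
    over compartment fractions f_k.  The summary p is the Bonferroni-scaled
    minimum of the per-compartment interaction p-values; the direction comes
    from the winning interaction coefficient's sign.
    """
    y = _as_binary(labels.loc[beta.columns])
    comp_cols = [c for c in compartments if c in fractions.columns]
    if len(comp_cols) < 2:
        raise ValueError("need >= 2 compartment fraction columns")
    F = fractions.loc[beta.columns, comp_cols].to_numpy(dtype=float)
    X = np.hstack([F, F * y[:, None]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fraction design matrix is collinear")
    B = beta.to_numpy(dtype=float)
    n, q = X.shape
    XtXinv = np.linalg.inv(X.T @ X)
    P = XtXinv @ X.T
    coefs = P @ B.T                     # q × probes
    resid = B.T - X @ coefs
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof
    kc = len(comp_cols)
    idx = np.arange(kc, 2 * kc)
    se = np.sqrt(np.outer(np.diag(XtXinv)[idx], sigma2))
    tstat = coefs[idx] / se
    p_int = 2.0 * stats.t.sf(np.abs(tstat), dof)   # kc × probes
    winner = np.argmin(p_int, axis=0)
    p_min = p_int[winner, np.arange(B.shape[0])]
    p_summary = np.minimum(p_min * kc, 1.0)
    win_coef = coefs[idx][winner, np.arange(B.shape[0])]
    out = pd.DataFrame(
        {
            "statistic": tstat[winner, np.arange(B.shape[0])],
            "p": p_summary,
            "direction": np.where(win_coef > 0, HYPER, HYPO),
            "compartment": [comp_cols[w] for w in winner],
            "flagged": ~np.isfinite(p_summary),
        },
        index=beta.index,
    )
    for c, comp in enumerate(comp_cols):
        out[f"p_{comp}"] = p_int[c]
        out[f"coef_{comp}"] = coefs[idx][c]
    out = _assign_ranks(out, np.where(np.isfinite(p_summary), p_summary, 1.0))
    out.attrs["method"] = "celldmc"
    return out


def aggregate_geometric_mean(rankings: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-method ranks by their geometric mean.

    Probes are ordered by ascending geometric-mean rank; ties are broken by
    the adjusted-logistic rank when that method is present (otherwise by the
    first supplied method's rank), then by probe id.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    methods = list(rankings)
    ref_idx = rankings[methods[0]].index
    for m in methods[1:]:
        if not rankings[m].index.sort_values().equals(ref_idx.sort_values()):
            diff = set(rankings[m].index) ^ set(ref_idx)
            raise ValueError(f"probe sets differ between methods: {sorted(diff)[:10]}")
    ranks = pd.DataFrame(
        {m: rankings[m]["rank"].reindex(ref_idx) for m in methods}, index=ref_idx
    )
    # multiply in sorted order so permuted method order gives bit-identical gm
    r_sorted = np.sort(ranks.to_numpy(dtype=float), axis=1)
    gm = np.prod(r_sorted, axis=1) ** (1.0 / r_sorted.shape[1])
    tiebreak_method = "adjusted_logistic" if "adjusted_logistic" in rankings else methods[0]
    out = ranks.add_prefix("rank_")
    out["gm_rank"] = gm
    order = np.lexsort((
        out.index.to_numpy(),
        out[f"rank_{tiebreak_method}"].to_numpy(),
        gm,
    ))
    final = np.empty(len(out), dtype=int)
    final[order] = np.arange(1, len(out) + 1)
    out["final_rank"] = final
    return out.sort_values("final_rank")
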