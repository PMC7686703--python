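"""Evaluation statistics: splits, ROC/AUC with CIs, trends, enrichment.

Covers the statistical scaffolding around the signature: the stratified
2/3–1/3 train/validation split, AUC by the Mann–Whitney formulation with
DeLong or stratified-bootstrap confidence intervals, Firth bias-reduced
association models for the index, within-group linear trends of the index
against age or IC, CpG-annotation Fisher enrichment, and subgroup AUCs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .firth import FirthLogit
from .ranking import fdr_adjust


# --- splitting -----------------------------------------------------------

def stratified_split(
    sample_sheet: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    age_bins: np.ndarray | None = None,
    ic_bins: np.ndarray | None = None,
    age_col: str = "age",
    ic_col: str = "IC",
    label_col: str = "label",
    seed: int = 0,
) -> pd.Series:
    """Assign samples to 'training'/'validation' within (age × IC × label) strata.

    Age defaults to decade bins and IC to its quartiles.  Within each
    stratum samples are shuffled (seeded) and the training share is the
    integer count closest to ``train_fraction``; singletons go to training.
    """
    rng = np.random.default_rng(seed)
    ages = sample_sheet[age_col].to_numpy(dtype=float)
    ics = sample_sheet[ic_col].to_numpy(dtype=float)
    if age_bins is None:
        lo = np.floor(ages.min() / 10) * 10
        hi = np.ceil(ages.max() / 10) * 10 + 10
        age_bins = np.arange(lo, hi + 1, 10)
    if ic_bins is None:
        ic_bins = np.unique(np.quantile(ics, [0.0, 0.25, 0.5, 0.75, 1.0]))
        if len(ic_bins) < 2:
            ic_bins = np.array([ics.min() - 1, ics.max() + 1])
    age_idx = np.digitize(ages, age_bins)
    ic_idx = np.digitize(ics, ic_bins)
    labels = sample_sheet[label_col].to_numpy()
    assignment = pd.Series("training", index=sample_sheet.index, name="set")
    strata = pd.DataFrame({"a": age_idx, "i": ic_idx, "l": labels},
                          index=sample_sheet.index)
    for _, members in strata.groupby(["a", "i", "l"], sort=True):
        ids = list(members.index)
        if len(ids) == 1:
            continue  # singleton stays in training
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1) if len(ids) > 1 else 1
        val_ids = [ids[k] for k in perm[n_train:]]
        assignment.loc[val_ids] = "validation"
    return assignment


# --- ROC / AUC -----------------------------------------------------------

def _binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        arr = (arr == "O").astype(float)
    return np.asarray(arr, dtype=float)


def roc_auc(scores, labels) -> float:
    """AUC via the Mann–Whitney pair count; ties credit ½."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_variance(scores, y):
    """DeLong placement-value variance of the AUC estimator."""
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # placements: V10_i = P(pos_i beats a random neg), V01_j symmetric
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(scores, labels, method: str = "delong", level: float = 0.95,
           n_boot: int = 2000, seed: int = 0) -> dict:
    """AUC with a confidence interval.

    ``delong``: normal-theory CI from the closed-form placement variance,
    truncated to [0, 1].  ``stratified_bootstrap``: resampling within each
    class, percentile interval.
    """
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    auc = roc_auc(s, y)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 5:
        raise ValueError("need >= 5 samples per class for a CI")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "delong":
        se = float(np.sqrt(_delong_variance(s, y)))
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif method == "stratified_bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = s[y == 1], s[y == 0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, n_pos, replace=True)
            ns = rng.choice(neg, n_neg, replace=True)
            boots[b] = roc_auc(
                np.concatenate([ps, ns]),
                np.concatenate([np.ones(n_pos), np.zeros(n_neg)]),
            )
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {
        "auc": auc, "ci_low": float(lo), "ci_high": float(hi),
        "method": method, "n_pos": n_pos, "n_neg": n_neg,
    }


def subgroup_auc(scores: pd.Series, labels: pd.Series,
                 masks: dict[str, pd.Series], method: str = "delong",
                 seed: int = 0) -> pd.DataFrame:
    """AUC (with CI) within each named sample subgroup.

    Subgroups where only one class survives are reported as NA with a
    warning rather than erroring the whole table.
    """
    rows = []
    for name, mask in masks.items():
        m = np.asarray(mask.loc[scores.index], dtype=bool)
        y = _binary(labels.loc[scores.index])[m]
        if len(np.unique(y)) < 2 or min(int(y.sum()), int(len(y) - y.sum())) < 5:
            warnings.warn(f"subgroup {name!r}: single class or too few; NA", stacklevel=2)
            rows.append((name, int(m.sum()), np.nan, np.nan, np.nan))
            continue
        res = auc_ci(scores[m], labels.loc[scores.index][m], method=method, seed=seed)
        rows.append((name, int(m.sum()), res["auc"], res["ci_low"], res["ci_high"]))
    return pd.DataFrame(rows, columns=["subgroup", "n", "auc", "ci_low", "ci_high"]
                        ).set_index("subgroup")


def preset_masks(sample_sheet: pd.DataFrame, age_col="age", ic_col="IC",
                 age_cut: float = 50.0, ic_cut: float = 0.5) -> dict[str, pd.Series]:
    """The standard subgroup masks: age < / ≥ 50 years and IC < / ≥ 0.5."""
    return {
        f"age<{age_cut:g}": sample_sheet[age_col] < age_cut,
        f"age>={age_cut:g}": sample_sheet[age_col] >= age_cut,
        f"ic<{ic_cut:g}": sample_sheet[ic_col] < ic_cut,
        f"ic>={ic_cut:g}": sample_sheet[ic_col] >= ic_cut,
    }


# --- Firth association scan ---------------------------------------------

def association_scan(
    index: pd.Series,
    sample_sheet: pd.DataFrame,
    adjustments: dict[str, list[str]] | None = None,
    label_col: str = "label",
) -> pd.DataFrame:
    """Firth-logistic association of the index with community type.

    One model per adjustment set (default: unadjusted, age, IC, age + IC);
    samples with missing covariates are dropped per model.  Returns one row
    per (model, covariate) with the bias-reduced OR, profile-penalized CI
    and penalized-LRT p.
    """
    if adjustments is None:
        adjustments = {
            "unadjusted": [],
            "age": ["age"],
            "ic": ["IC"],
            "age+ic": ["age", "IC"],
        }
    rows = []
    y_all = (sample_sheet[label_col] == "O").astype(float)
    for model_name, covs in adjustments.items():
        missing = [c for c in covs if c not in sample_sheet.columns]
        if missing:
            raise ValueError(f"covariate(s) absent from sample sheet: {missing}")
        data = pd.concat([index.rename("index"), sample_sheet[covs], y_all.rename("_y")],
                         axis=1).dropna()
        X = data[["index"] + covs].to_numpy()
        fit = FirthLogit(data["_y"].to_numpy(), X, names=["index"] + covs).fit()
        for term, row in fit.table.iterrows():
            if term == "intercept":
                continue
            rows.append((model_name, term, row["estimate"], row["OR"],
                         row["ci_low"], row["ci_high"], row["p"], len(data)))
    return pd.DataFrame(rows, columns=["model", "term", "estimate", "OR",
                                       "ci_low", "ci_high", "p", "n"])


# --- trends ---------------------------------------------------------------

def linear_trend(index: pd.Series, covariate: pd.Series, group_mask=None,
                 covariate_name: str = "covariate", group_label: str = "all") -> dict:
    """OLS of the index on one covariate within a sample subset."""
    x = covariate.loc[index.index].to_numpy(dtype=float)
    v = index.to_numpy(dtype=float)
    if group_mask is not None:
        m = np.asarray(group_mask.loc[index.index], dtype=bool)
        x, v = x[m], v[m]
    if len(x) < 3:
        raise ValueError("need >= 3 samples for a trend fit")
    if np.ptp(x) <= 0:
        raise ValueError(f"covariate {covariate_name!r} is constant in group")
    fit = stats.linregress(x, v)
    return {
        "intercept": float(fit.intercept), "slope": float(fit.slope),
        "slope_p": float(fit.pvalue), "covariate": covariate_name,
        "group": group_label, "n": len(x),
    }


# --- annotation enrichment -------------------------------------------------

def annotation_enrichment(
    selected: set[str], background: set[str], annotation: pd.Series
) -> pd.DataFrame:
    """Fisher-exact enrichment of the selected probes per annotation category.

    ``annotation`` maps probe → category (island/shore/shelf/open_sea or gene
    region); unannotated probes fall into 'unknown'.  The 2×2 table per
    category is (selected vs background-remainder) × (in vs out of
    category); p-values are BH-adjusted across categories.
    """
    selected, background = set(selected), set(background)
    if not selected <= background:
        raise ValueError("selected probes must be a subset of the background")
    ann = {p: annotation.get(p, "unknown") for p in background}
    rest = background - selected
    cats = sorted(set(ann.values()))
    rows = []
    for cat in cats:
        a = sum(1 for p in selected if ann[p] == cat)
        b = len(selected) - a
        c = sum(1 for p in rest if ann[p] == cat)
        d = len(rest) - c
        if a == 0 and c == 0:
            rows.append((cat, a, b, c, d, np.nan, np.nan))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cat, a, b, c, d, float(odds), float(p)))
    out = pd.DataFrame(
        rows,
        columns=["category", "selected_in", "selected_out",
                 "rest_in", "rest_out", "odds_ratio", "p"],
    ).set_index("category")
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = fdr_adjust(out.loc[mask, "p"].to_numpy())
    return out
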