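"""Signature training: the WID-LO index and its nonlinear variant.

`SignatureModel` holds a training cohort (beta matrix, L/O labels, immune
cell proportions and a probe ranking).  `fit()` scans feature pools taken
from the top of the ranking and, for each pool size and each elastic-net
mixing value α, cross-validates the penalized logistic λ path; the
(pool, α, λ) triple with the best mean validation AUC is refit on the full
training data and returned as a `SignatureResults`, whose linear predictor
on new samples is the WID-LO index (log-odds of an O-type community; class
encoding O = 1, L = 0).

In nonlinear mode every pooled probe also contributes a second-order β×IC
interaction column, and the ℓ1 penalty decides which survive.
"""

from __future__ import annotations

import hashlib
import io
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluate import roc_auc
from .penalized import default_lambdas, enet_logistic_path
from .ranking import _as_binary

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


class FeatureSpec:
    """Ordered list of design terms: linear(probe) and interaction(probe × IC)."""

    def __init__(self, pool: list[str], nonlinear: bool):
        self.pool = list(pool)
        if len(set(self.pool)) != len(self.pool):
            raise ValueError("duplicate probes in feature pool")
        self.nonlinear = bool(nonlinear)
        self.terms: list[tuple[str, str]] = [("linear", p) for p in self.pool]
        if self.nonlinear:
            self.terms += [("interaction", p) for p in self.pool]

    @property
    def pool_size(self) -> int:
        return len(self.pool)

    def column_names(self) -> list[str]:
        return [p if t == "linear" else f"{p}:IC" for t, p in self.terms]


def build_design_matrix(
    beta: pd.DataFrame, ic: pd.Series, pool: list[str], nonlinear: bool = False
) -> tuple[pd.DataFrame, FeatureSpec]:
    """Samples × terms design: β columns for the pool, then β×IC columns."""
    missing = [p for p in pool if p not in beta.index]
    if missing:
        raise ValueError(f"probes absent from beta matrix: {missing[:10]}")
    spec = FeatureSpec(pool, nonlinear)
    lin = beta.loc[pool].T  # samples × probes
    blocks = [lin.to_numpy(dtype=float)]
    if nonlinear:
        icv = np.asarray(ic.loc[beta.columns], dtype=float)
        blocks.append(blocks[0] * icv[:, None])
    X = pd.DataFrame(
        np.hstack(blocks), index=beta.columns, columns=spec.column_names()
    )
    return X, spec


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int, max_attempts: int = 10):
    """Label-stratified CV folds; re-drawn (sub-seeded) if a fold is single-class."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
            for tr, va in folds
        )
        if ok:
            if attempt:
                warnings.warn(f"folds re-drawn {attempt} time(s)", stacklevel=2)
            return folds
    raise ValueError("could not draw folds with both classes present")


class SignatureModel:
    """Penalized-logistic signature model of community type from methylation.

    Parameters
    ----------
    beta
        Probes × samples training beta matrix (complete, QC'd).
    labels
        'L'/'O' per sample (index aligned with beta columns).
    ic
        Immune cell proportion per sample.
    ranking
        Probe ordering driving the feature pools: either an aggregated
        ranking (with ``final_rank``) or a single-method ranking (with
        ``rank``); strongest probe first.
    nonlinear
        Add β×IC second-order terms for every pooled probe.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        labels: pd.Series,
        ic: pd.Series,
        ranking: pd.DataFrame,
        nonlinear: bool = False,
    ):
        self.beta = beta
        self.labels = labels.loc[beta.columns]
        self.ic = ic.loc[beta.columns]
        rank_col = "final_rank" if "final_rank" in ranking.columns else "rank"
        self.ranked_probes = list(ranking.sort_values(rank_col).index)
        missing = set(self.ranked_probes) - set(beta.index)
        if missing:
            raise ValueError(f"ranking contains probes absent from beta: {sorted(missing)[:10]}")
        self.nonlinear = bool(nonlinear)
        self.y = _as_binary(self.labels)

    def fit(
        self,
        pool_grid: tuple[int, ...] = (1000, 2000, 5000, 10000, 20000, 50000),
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        n_folds: int = 10,
        n_lambda: int = 50,
        lambda_min_ratio: float = 1e-2,
        lambda_rule: str = "max",
        tol: float = 1e-6,
        seed: int = 0,
    ) -> "SignatureResults":
        """Cross-validated (pool, α, λ) scan, then a full-data refit.

        ``lambda_rule``: 'max' picks the λ with the best mean CV AUC; '1se'
        the sparsest λ within one standard error of it.
        """
        pools = sorted({p for p in pool_grid if 1 <= p} | set())
        pools = [min(p, len(self.ranked_probes)) for p in pools]
        pools = sorted(set(pools))
        if not pools:
            raise ValueError("empty pool grid")
        if n_folds < 3:
            raise ValueError("need at least 3 folds")
        folds = _stratified_folds(self.y, n_folds, seed)
        profile_rows = []
        best = None  # (auc, pool, alpha, lam, lambdas)
        for pool_size in pools:
            pool = self.ranked_probes[:pool_size]
            X, spec = build_design_matrix(self.beta, self.ic, pool, self.nonlinear)
            Xv = X.to_numpy()
            for alpha in alpha_grid:
                mean_x = Xv.mean(axis=0)
                sd_x = Xv.std(axis=0)
                Xs = (Xv - mean_x) / np.where(sd_x > 0, sd_x, 1.0)
                lambdas = default_lambdas(Xs, self.y, alpha, n_lambda=n_lambda,
                                          lambda_min_ratio=lambda_min_ratio)
                fold_auc = np.full((n_folds, len(lambdas)), np.nan)
                for fi, (tr, va) in enumerate(folds):
                    path = enet_logistic_path(Xv[tr], self.y[tr], alpha,
                                              lambdas=lambdas, tol=tol)
                    for li in range(len(lambdas)):
                        scores = path.predict_linear(Xv[va], li)
                        fold_auc[fi, li] = roc_auc(scores, self.y[va])
                mean_auc = fold_auc.mean(axis=0)
                se_auc = fold_auc.std(axis=0, ddof=1) / np.sqrt(n_folds)
                li_best = int(np.argmax(mean_auc))
                if lambda_rule == "1se":
                    thresh = mean_auc[li_best] - se_auc[li_best]
                    li_sel = int(np.flatnonzero(mean_auc >= thresh)[0])
                else:
                    li_sel = li_best
                for li in range(len(lambdas)):
                    profile_rows.append(
                        (pool_size, alpha, lambdas[li], mean_auc[li], se_auc[li])
                    )
                # ties: smaller pool, then smaller α (the grouping effect keeps
                # correlated CpGs together), then larger λ (argmax takes the
                # first, i.e. most regularized, λ at equal CV AUC)
                cand = (mean_auc[li_sel], -pool_size, -alpha, lambdas[li_sel], lambdas)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        best_auc, neg_pool, neg_alpha, best_lambda, best_lambdas = best
        best_pool_size, best_alpha = -neg_pool, -neg_alpha
        pool = self.ranked_probes[:best_pool_size]
        X, spec = build_design_matrix(self.beta, self.ic, pool, self.nonlinear)
        lam_seq = best_lambdas[best_lambdas >= best_lambda]
        path = enet_logistic_path(X.to_numpy(), self.y, best_alpha,
                                  lambdas=lam_seq, tol=tol)
        weights = pd.Series(path.coefs[:, -1], index=X.columns)
        cv_profile = pd.DataFrame(
            profile_rows, columns=["pool_size", "alpha", "lambda", "cv_auc", "cv_auc_se"]
        )
        return SignatureResults(
            spec=spec,
            weights=weights,
            intercept=float(path.intercepts[-1]),
            alpha=float(best_alpha),
            lambda_=float(best_lambda),
            cv_auc=float(best_auc),
            cv_profile=cv_profile,
            seed=seed,
            training_hash=_hash_training(self.beta, self.labels),
        )


def _hash_training(beta: pd.DataFrame, labels: pd.Series) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(beta.to_numpy()).tobytes())
    h.update(",".join(map(str, labels)).encode())
    return h.hexdigest()[:16]


class SignatureResults:
    """A trained WID-LO (or NL WID-LO) signature.

    ``predict`` evaluates the index — intercept + Σ term weights × features —
    for new samples; higher values favour an O-type community.
    """

    def __init__(self, spec, weights, intercept, alpha, lambda_, cv_auc,
                 cv_profile, seed=0, training_hash=""):
        self.spec = spec
        self.weights = weights
        self.intercept = intercept
        self.alpha = alpha
        self.lambda_ = lambda_
        self.cv_auc = cv_auc
        self.cv_profile = cv_profile
        self.seed = seed
        self.training_hash = training_hash

    @property
    def n_nonzero(self) -> int:
        return int((self.weights != 0).sum())

    @property
    def nonzero_terms(self) -> pd.Series:
        return self.weights[self.weights != 0]

    def predict(self, beta: pd.DataFrame, ic: pd.Series | None = None) -> pd.Series:
        """WID-LO index per sample (log-odds scale)."""
        needed = sorted({p for (t, p), w in zip(self.spec.terms, self.weights) if w != 0})
        missing = [p for p in needed if p not in beta.index]
        if missing:
            raise ValueError(f"required probes missing from beta: {missing[:10]}")
        icv = None
        if self.spec.nonlinear:
            if ic is None:
                raise ValueError("nonlinear signature requires IC values")
            icv = np.asarray(ic.loc[beta.columns], dtype=float)
        idx = np.full(beta.shape[1], self.intercept)
        for (term, probe), w in zip(self.spec.terms, self.weights):
            if w == 0:
                continue
            col = beta.loc[probe].to_numpy(dtype=float)
            if term == "interaction":
                col = col * icv
            idx = idx + w * col
        return pd.Series(idx, index=beta.columns, name="wid_lo_index")

    def summary(self) -> str:
        kind = "NL WID-LO" if self.spec.nonlinear else "WID-LO"
        lines = [
            f"{kind} signature",
            "=" * 40,
            f"pool size:          {self.spec.pool_size}",
            f"alpha:              {self.alpha:.2f}",
            f"lambda:             {self.lambda_:.6g}",
            f"mean CV AUC:        {self.cv_auc:.4f}",
            f"terms (total):      {len(self.spec.terms)}",
            f"terms (nonzero):    {self.n_nonzero}",
            f"  linear:           {sum(1 for (t, _), w in zip(self.spec.terms, self.weights) if w and t == 'linear')}",
            f"  interaction:      {sum(1 for (t, _), w in zip(self.spec.terms, self.weights) if w and t == 'interaction')}",
            f"intercept:          {self.intercept:.6g}",
            f"training hash:      {self.training_hash}",
        ]
        return "\n".join(lines)

    # --- persistence -----------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# alpha\t{self.alpha!r}\n")
        buf.write(f"# lambda\t{self.lambda_!r}\n")
        buf.write(f"# pool_size\t{self.spec.pool_size}\n")
        buf.write(f"# nonlinear\t{int(self.spec.nonlinear)}\n")
        buf.write(f"# cv_auc\t{self.cv_auc!r}\n")
        buf.write(f"# seed\t{self.seed}\n")
        buf.write(f"# training_hash\t{self.training_hash}\n")
        buf.write("term_type\tprobe\tweight\n")
        buf.write(f"intercept\t.\t{self.intercept!r}\n")
        for (term, probe), w in zip(self.spec.terms, self.weights):
            buf.write(f"{term}\t{probe}\t{w!r}\n")
        return buf.getvalue()

    @classmethod
    def load(cls, path) -> "SignatureResults":
        meta: dict[str, str] = {}
        rows: list[tuple[str, str, float]] = []
        intercept = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    try:
                        key, value = line[1:].strip().split("\t")
                    except ValueError as exc:
                        raise ValueError(f"malformed metadata at line {lineno}") from exc
                    meta[key] = value
                    continue
                parts = line.split("\t")
                if parts == ["term_type", "probe", "weight"]:
                    continue
                if len(parts) != 3:
                    raise ValueError(f"malformed term row at line {lineno}")
                term, probe, weight = parts
                if term == "intercept":
                    intercept = float(weight)
                elif term in ("linear", "interaction"):
                    rows.append((term, probe, float(weight)))
                else:
                    raise ValueError(f"unknown term type {term!r} at line {lineno}")
        if intercept is None:
            raise ValueError("signature file lacks an intercept row")
        pool = [p for t, p, _ in rows if t == "linear"]
        nonlinear = meta.get("nonlinear", "0") == "1"
        spec = FeatureSpec(pool, nonlinear)
        wmap = {(t, p): w for t, p, w in rows}
        weights = pd.Series(
            [wmap.get(term, 0.0) for term in spec.terms],
            index=spec.column_names(),
        )
        return cls(
            spec=spec,
            weights=weights,
            intercept=intercept,
            alpha=float(meta.get("alpha", "nan")),
            lambda_=float(meta.get("lambda", "nan")),
            cv_auc=float(meta.get("cv_auc", "nan")),
            cv_profile=pd.DataFrame(),
            seed=int(meta.get("seed", "0")),
            training_hash=meta.get("training_hash", ""),
        )
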