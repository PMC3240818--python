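"""Ridge-penalized logistic classification of LV dysfunction from gene subsets.

The estimator mirrors the classic data-mining setup for small gene panels:
logistic regression with a tiny ridge penalty (default 1e-8) that leaves the
fit essentially unpenalized but keeps weights finite on separable data.  It is
exposed statsmodels-style: :class:`RidgeLogit` is built from data and
``fit()`` returns a :class:`RidgeLogitResults` carrying estimates, Wald
standard errors and a ``summary()`` table.

Gene subsets are scored by stratified 10-fold cross-validation: out-of-fold
probabilities are pooled into a single ROC, and every subset up to a maximal
size is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import ClassificationTable, confusion_at_threshold, roc_auc

DEFAULT_RIDGE = 1e-8


class RidgeLogit:
    """Binary logistic regression with an L2 penalty on the slopes.

    Minimizes ``-loglik + (ridge / 2) * ||w||^2`` (intercept unpenalized) by
    iteratively reweighted least squares.

    Parameters
    ----------
    endog : array-like of bool/0-1
        Outcome; True / 1 codes the positive (low EF) class.
    exog : array-like, shape (n, p)
        Feature matrix without a constant column; an intercept is added.
    ridge : float
        Penalty constant; 0 gives plain maximum likelihood.
    """

    def __init__(self, endog, exog, ridge: float = DEFAULT_RIDGE, feature_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        self.ridge = float(ridge)
        if not np.isfinite(exog).all():
            raise ValueError("features must be finite (impute upstream)")
        if len(self.endog) != exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        uniq = np.unique(self.endog)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("endog must be binary 0/1")
        if len(uniq) < 2:
            raise ValueError("endog contains a single class")
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"x{i}" for i in range(exog.shape[1])]

    def _objective(self, X, y, pen, beta):
        eta = np.clip(X @ beta, -500.0, 500.0)
        # -loglik + ridge/2 * ||slopes||^2, numerically stable log1p form
        nll = np.sum(np.log1p(np.exp(-np.abs(eta))) + np.where(eta > 0, 0.0, -eta)
                     + (1.0 - y) * eta)
        return nll + 0.5 * np.sum(pen * beta**2)

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "RidgeLogitResults":
        y = self.endog
        X = np.column_stack([np.ones(len(y)), self.exog])
        p_dim = X.shape[1]
        pen = np.full(p_dim, self.ridge)
        pen[0] = 0.0  # intercept unpenalized
        beta = np.zeros(p_dim)
        obj = self._objective(X, y, pen, beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = np.clip(X @ beta, -500.0, 500.0)
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = X.T @ (mu - y) + pen * beta
            hess = (X * w[:, None]).T @ X + np.diag(pen + 1e-12)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # damped Newton: halve the step until the penalized deviance drops
            scale = 1.0
            for _ in range(30):
                cand = beta - scale * step
                cand_obj = self._objective(X, y, pen, cand)
                if cand_obj <= obj + 1e-12:
                    break
                scale *= 0.5
            else:
                converged = True  # no descent direction left: at the optimum
                break
            beta, obj = cand, cand_obj
            if np.max(np.abs(scale * step)) < tol:
                converged = True
                break
        eta = np.clip(X @ beta, -500.0, 500.0)
        mu = expit(eta)
        llf = float(np.sum(y * np.log(np.clip(mu, 1e-12, 1)) +
                           (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))))
        w = mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X + np.diag(pen + 1e-12)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        return RidgeLogitResults(self, beta, cov, llf, converged, n_iter)


@dataclass
class RidgeLogitResults:
    """Fitted ridge-logistic model: coefficients, Wald inference, prediction."""

    model: RidgeLogit
    _beta: np.ndarray
    _cov: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=["const"] + self.model.feature_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self._cov), 0, None)),
                         index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        from scipy.stats import norm
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self._beta / np.sqrt(np.clip(np.diag(self._cov), 1e-300, None))
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    def predict(self, exog) -> np.ndarray:
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        X = np.column_stack([np.ones(exog.shape[0]), exog])
        return expit(np.clip(X @ self._beta, -500.0, 500.0))

    def summary(self) -> str:
        df = pd.DataFrame({"coef": self.params, "std err": self.bse, "P>|z|": self.pvalues})
        head = (f"Ridge logistic regression (ridge={self.model.ridge:g}, "
                f"n={len(self.model.endog)}, llf={self.llf:.4f}, "
                f"converged={self.converged} in {self.n_iter} it)\n")
        return head + df.to_string(float_format=lambda v: f"{v: .6g}")


@dataclass
class SubsetEvaluation:
    """A candidate gene subset with pooled out-of-fold CV performance."""

    feature_ids: tuple
    fold_assignment: pd.Series
    oof_probabilities: pd.Series
    auc: float
    tpr: float
    fpr: float
    table: ClassificationTable
    threshold: float = 0.5


def stratified_folds(labels, k: int, seed: int | None = 0) -> np.ndarray:
    """Seeded stratified fold assignment (class proportions preserved +/- 1)."""
    y = np.asarray(labels, dtype=bool)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError("k exceeds the number of samples")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class for stratified CV")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    offset = 0
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger classes so small folds stay mixed
    return folds


def _fold_stats(X: np.ndarray, train: np.ndarray):
    """Training-fold per-feature mean (for imputation/centering) and sd."""
    sub = X[train]
    mean = np.nanmean(sub, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    sd = np.nanstd(sub, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd) & (sd > 1e-8), sd, 1.0)
    return mean, sd


def cross_validated_probabilities(
    features: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int | None = 0,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = 0.5,
) -> SubsetEvaluation:
    """Pooled out-of-fold probabilities of low EF for one feature set.

    Folds are stratified and seeded.  Within each fold the model is trained on
    the complement; missing values are imputed by training-fold feature means
    and features standardized with training-fold parameters only, so no
    information leaks from the held-out samples.
    """
    y = np.asarray(labels, dtype=bool)
    X = features.to_numpy(dtype=float)
    folds = stratified_folds(y, k, seed)
    oof = np.full(len(y), np.nan)
    for f in range(k):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contained a single class")
        mean, sd = _fold_stats(X, train)
        Xtr = (np.where(np.isfinite(X[train]), X[train], mean) - mean) / sd
        Xte = (np.where(np.isfinite(X[test]), X[test], mean) - mean) / sd
        res = RidgeLogit(y[train].astype(float), Xtr, ridge=ridge).fit()
        oof[test] = res.predict(Xte)
    tpr, fpr, table = confusion_at_threshold(oof, y, threshold)
    return SubsetEvaluation(
        feature_ids=tuple(features.columns),
        fold_assignment=pd.Series(folds, index=features.index),
        oof_probabilities=pd.Series(oof, index=features.index),
        auc=roc_auc(oof, y),
        tpr=tpr,
        fpr=fpr,
        table=table,
    )


def subset_search(
    candidate_genes,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    max_size: int = 3,
    k: int = 10,
    seed: int | None = 0,
    include_full: bool = True,
    ridge: float = DEFAULT_RIDGE,
):
    """Exhaustively evaluate every candidate-gene subset of size 1..max_size.

    Candidates absent from the expression matrix are excluded up front and
    reported.  All subsets share one seeded fold assignment so AUCs are
    comparable.  With ``include_full`` the complete candidate panel is also
    evaluated.  Returns ``(ranked, missing)`` with evaluations ordered by AUC
    descending, then smaller size, then lexicographic gene ids.
    """
    candidates = list(dict.fromkeys(candidate_genes))
    if not candidates:
        raise ValueError("candidate list is empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    missing = [g for g in candidates if g not in expr.index]
    present = sorted(g for g in candidates if g in expr.index)
    if not present:
        return [], missing
    max_size = min(max_size, len(present))

    y = (samples.loc[expr.columns, "ef_class"] == "low").to_numpy()
    folds = stratified_folds(y, k, seed)
    X_all = expr.loc[present].to_numpy(dtype=float).T  # samples x genes
    col_of = {g: i for i, g in enumerate(present)}

    fold_masks = [(folds == f) for f in range(k)]
    stats = []
    for test in fold_masks:
        stats.append(_fold_stats(X_all, ~test))

    def evaluate(genes: tuple) -> SubsetEvaluation:
        cols = [col_of[g] for g in genes]
        Xs = X_all[:, cols]
        oof = np.full(len(y), np.nan)
        for f, test in enumerate(fold_masks):
            train = ~test
            mean, sd = stats[f]
            mean_s, sd_s = mean[cols], sd[cols]
            Xtr = (np.where(np.isfinite(Xs[train]), Xs[train], mean_s) - mean_s) / sd_s
            Xte = (np.where(np.isfinite(Xs[test]), Xs[test], mean_s) - mean_s) / sd_s
            res = RidgeLogit(y[train].astype(float), Xtr, ridge=ridge).fit()
            oof[test] = res.predict(Xte)
        tpr, fpr, table = confusion_at_threshold(oof, y, 0.5)
        return SubsetEvaluation(
            feature_ids=genes,
            fold_assignment=pd.Series(folds, index=expr.columns),
            oof_probabilities=pd.Series(oof, index=expr.columns),
            auc=roc_auc(oof, y),
            tpr=tpr,
            fpr=fpr,
            table=table,
        )

    subsets = []
    for size in range(1, max_size + 1):
        subsets.extend(itertools.combinations(present, size))
    if include_full and len(present) > max_size:
        subsets.append(tuple(present))

    evaluations = [evaluate(genes) for genes in subsets]
    evaluations.sort(key=lambda e: (-e.auc, len(e.feature_ids), e.feature_ids))
    return evaluations, missing
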