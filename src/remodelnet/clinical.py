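"""Validation-cohort statistics: association tests, single-marker prognosis,
multivariable clinical models, classification tables and net reclassification.

Cases are patients with LV dysfunction (EF <= 40%, class "low"); controls have
preserved function (EF > 40%, class "high").  "Up" reclassification means
crossing the probability threshold toward the predicted high-risk (low EF)
class.  The net reclassification index is

    NRI = [Pr(up|case) - Pr(down|case)] - [Pr(up|control) - Pr(down|control)]

reported in percent.  Exact small-sample enumeration backs the rank tests
because the usual exact methods do not cover midrank ties.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import (  # noqa: F401  (re-exported validation surface)
    ClassificationTable,
    classification_table_metrics,
    roc_auc,
)
from .modeling import DEFAULT_RIDGE, RidgeLogit, RidgeLogitResults

DEFAULT_COVARIATES = ("age", "sex", "time_to_reperfusion")


# ---------------------------------------------------------------------------
# rank and exact tests
# ---------------------------------------------------------------------------

def spearman_association(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided p-value.

    For n <= 9 the p-value is exact, by enumerating all rank permutations;
    beyond that the usual t approximation is used.  Constant input makes rho
    undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p_t = sps.spearmanr(x, y)
    n = len(x)
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
        rho_perm = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_t)


def mann_whitney_test(group_a, group_b) -> tuple[float, float]:
    """Midrank Mann-Whitney U of group_a with a two-sided p-value.

    Exact by enumeration over all C(n, n_a) group assignments when the
    combined sample size is <= 12 (handles ties through midranks), else the
    tie-corrected normal approximation.  Satisfies U(a,b) + U(b,a) = n_a*n_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0
    if n_a + n_b <= 12:
        n = n_a + n_b
        devs = []
        for idx in itertools.combinations(range(n), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
            devs.append(abs(u - mu))
        devs = np.array(devs)
        p = float(np.mean(devs >= abs(u_obs - mu) - 1e-12))
        return u_obs, p
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher exact two-sided p and the sample odds ratio for a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("every margin must be positive")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(p), float(odds)


# ---------------------------------------------------------------------------
# marker and clinical models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerAssociation:
    """Single-marker association: slope, Wald p, and the marker's ROC AUC."""

    form: str
    slope: float
    p_value: float
    auc: float


def _oriented_auc(marker: np.ndarray, y_low: np.ndarray) -> float:
    """Marker AUC for the low-EF class, oriented by its association sign."""
    if np.ptp(marker) == 0:
        return 0.5
    direction = marker[y_low].mean() - marker[~y_low].mean()
    score = marker if direction >= 0 else -marker
    return roc_auc(score, y_low)


def marker_association(marker, outcome: pd.DataFrame, form: str = "linear") -> MarkerAssociation:
    """Association of one biomarker with LV function.

    ``form='linear'`` regresses EF% on the marker (slope and Wald p from OLS);
    ``form='logistic'`` fits the low-EF class on the marker.  Either way the
    marker's discrimination is summarized by its ROC AUC for the low-EF class,
    oriented so that the AUC reflects the marker's own association direction.
    """
    m = np.asarray(marker, dtype=float)
    if len(m) != len(outcome):
        raise ValueError("marker and outcome lengths differ")
    if len(m) < 10:
        raise ValueError("need n >= 10")
    y_low = (outcome["ef_class"] == "low").to_numpy()
    if form == "linear":
        import statsmodels.api as sm
        if np.ptp(m) == 0:
            slope, p = 0.0, 1.0
        else:
            ef = outcome["ef_percent"].to_numpy(dtype=float)
            res = sm.OLS(ef, sm.add_constant(m)).fit()
            slope, p = float(res.params[1]), float(res.pvalues[1])
    elif form == "logistic":
        if y_low.all() or not y_low.any():
            raise ValueError("single-class outcome")
        if np.ptp(m) == 0:
            slope, p = 0.0, 1.0
        else:
            res = RidgeLogit(y_low.astype(float), (m - m.mean()) / (m.std(ddof=1) or 1.0),
                             ridge=DEFAULT_RIDGE).fit()
            slope, p = float(res.params.iloc[1]), float(res.pvalues.iloc[1])
    else:
        raise ValueError("form must be 'linear' or 'logistic'")
    return MarkerAssociation(form=form, slope=slope, p_value=p,
                             auc=_oriented_auc(m, y_low))


def _design_matrix(samples: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex_female"] = (samples["sex"] == "female").astype(float)
        else:
            if cov not in samples.columns:
                raise ValueError(f"covariate {cov!r} missing from sample table")
            cols[cov] = samples[cov].astype(float)
    return pd.DataFrame(cols, index=samples.index)


class ClinicalModel:
    """Multivariable logistic model of LV dysfunction on clinical covariates.

    Default covariates are age, sex and time to reperfusion; a biomarker
    column can be appended with ``marker=``.  Fitted with a tiny ridge so a
    marker duplicating a covariate degrades the Wald inference (which is
    flagged) but not the fitted probabilities.
    """

    def __init__(self, samples: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                 marker: str | None = None, ridge: float = DEFAULT_RIDGE):
        self.samples = samples
        design = _design_matrix(samples, covariates)
        if marker is not None:
            design[marker] = samples[marker].astype(float)
        if design.isna().any().any():
            raise ValueError("covariates contain missing values")
        sds = design.std(ddof=0)
        degenerate = sds[sds == 0].index.tolist()
        if degenerate:
            raise ValueError(f"constant covariate(s): {degenerate}")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            warnings.warn("collinear design; coefficients are not individually "
                          "identified (fit is ridge-regularized)", stacklevel=2)
        self.design = design
        self.ridge = ridge
        self.y_low = (samples["ef_class"] == "low").to_numpy()
        if self.y_low.all() or not self.y_low.any():
            raise ValueError("both EF classes must be present")

    def fit(self) -> "ClinicalModelResults":
        center = self.design.mean()
        scale = self.design.std(ddof=1).replace(0.0, 1.0)
        Z = (self.design - center) / scale
        res = RidgeLogit(self.y_low.astype(float), Z.to_numpy(),
                         ridge=self.ridge, feature_names=list(Z.columns)).fit()
        probs = res.predict(Z.to_numpy())
        return ClinicalModelResults(self, res, pd.Series(probs, index=self.design.index))


@dataclass
class ClinicalModelResults:
    """Fitted clinical model with discrimination and classification summaries."""

    model: ClinicalModel
    _fit: RidgeLogitResults
    probabilities: pd.Series

    @property
    def params(self) -> pd.Series:
        return self._fit.params

    @property
    def pvalues(self) -> pd.Series:
        return self._fit.pvalues

    @property
    def auc(self) -> float:
        return roc_auc(self.probabilities.to_numpy(), self.model.y_low)

    def classification_table(self, threshold: float = 0.5) -> ClassificationTable:
        from .metrics import confusion_at_threshold
        _, _, table = confusion_at_threshold(self.probabilities.to_numpy(),
                                             self.model.y_low, threshold)
        return table

    def summary(self) -> str:
        table = self.classification_table()
        lines = [self._fit.summary(), "",
                 f"AUC (fitted probabilities): {self.auc:.3f}",
                 "Classification at p >= 0.5 (true x predicted):",
                 table.counts.to_string(),
                 f"Correct: high {table.per_class_correct_rounded['high']}%, "
                 f"low {table.per_class_correct_rounded['low']}%, "
                 f"total {table.total_correct_rounded}%"]
        return "\n".join(lines)


def clinical_model(samples: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                   add_marker: str | None = None) -> ClinicalModelResults:
    """Convenience wrapper: build and fit a :class:`ClinicalModel`."""
    return ClinicalModel(samples, covariates=covariates, marker=add_marker).fit()


# ---------------------------------------------------------------------------
# reclassification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReclassificationResult:
    """NRI (in percent) with the per-class movement fractions behind it."""

    nri: float
    case_up: float
    case_down: float
    control_up: float
    control_down: float
    mode: str


def nri_individual(old_probabilities, new_probabilities, labels,
                   threshold: float = 0.5) -> ReclassificationResult:
    """Net reclassification index from paired individual probabilities.

    "Up" means the new model crosses the threshold toward predicted low EF.
    Movements are counted within cases (true low EF) and controls separately
    and combined by the NRI formula; the result is in percent.
    """
    old = np.asarray(old_probabilities, dtype=float)
    new = np.asarray(new_probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old/new probabilities and labels must be paired")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    old_pos = old >= threshold
    new_pos = new >= threshold
    up = ~old_pos & new_pos
    down = old_pos & ~new_pos
    case_up = up[y].mean()
    case_down = down[y].mean()
    control_up = up[~y].mean()
    control_down = down[~y].mean()
    nri = 100.0 * ((case_up - case_down) - (control_up - control_down))
    return ReclassificationResult(nri=float(nri), case_up=float(case_up),
                                  case_down=float(case_down),
                                  control_up=float(control_up),
                                  control_down=float(control_down),
                                  mode="individual")


def nri_net_from_tables(old: ClassificationTable, new: ClassificationTable) -> ReclassificationResult:
    """Net-movement NRI approximated from two marginal classification tables.

    Individual crossings are unobservable from marginals, so this reports the
    *net* movement: change in correctly classified cases over n_cases plus the
    drop in misclassified controls over n_controls.  It equals the individual
    NRI only when movement within each class is unidirectional.
    """
    if not old.class_totals.equals(new.class_totals):
        raise ValueError("old and new tables must share true-class totals")
    n_controls = float(old.class_totals["high"])
    n_cases = float(old.class_totals["low"])
    case_net = (float(new.counts.loc["low", "low"]) - float(old.counts.loc["low", "low"])) / n_cases
    control_net = (float(old.counts.loc["high", "low"]) - float(new.counts.loc["high", "low"])) / n_controls
    nri = 100.0 * (case_net + control_net)
    return ReclassificationResult(
        nri=float(nri),
        case_up=max(case_net, 0.0), case_down=max(-case_net, 0.0),
        control_up=max(-control_net, 0.0), control_down=max(control_net, 0.0),
        mode="net-from-tables",
    )
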