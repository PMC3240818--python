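"""Classifier performance metrics shared by the modeling and validation layers.

Conventions: the *positive* class is predicted left-ventricular dysfunction
(EF <= 40%, the "low" class).  Classification tables are stored as
true-class x predicted-class counts with rows/columns ordered (high, low).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CLASSES = ("high", "low")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching how clinical tables are reported."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the midrank Mann-Whitney statistic.

    ``AUC = (concordant + 0.5 * tied) / (n_pos * n_neg)`` where a pair is one
    positive (label True / low EF) and one negative sample.  Ties in the
    scores contribute half a concordance, so all-tied scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have identical length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes to be present")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class ClassificationTable:
    """2x2 true-class x predicted-class counts with percent-correct summaries.

    ``counts`` has rows indexed by the true class and columns by the
    predicted class, both ordered ``(high, low)``.
    """

    counts: pd.DataFrame

    @staticmethod
    def from_counts(counts) -> "ClassificationTable":
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table of counts")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        df = pd.DataFrame(
            arr,
            index=pd.Index(CLASSES, name="true"),
            columns=pd.Index(CLASSES, name="predicted"),
        )
        return ClassificationTable(df)

    @property
    def n(self) -> float:
        return float(self.counts.to_numpy().sum())

    @property
    def class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def per_class_correct(self) -> pd.Series:
        """Unrounded percent correctly classified within each true class."""
        totals = self.class_totals
        if (totals == 0).any():
            raise ValueError("each true class must be non-empty")
        diag = pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index)
        return 100.0 * diag / totals

    @property
    def total_correct(self) -> float:
        return float(100.0 * np.diag(self.counts.to_numpy()).sum() / self.n)

    @property
    def per_class_correct_rounded(self) -> pd.Series:
        return self.per_class_correct.map(round_half_up)

    @property
    def total_correct_rounded(self) -> float:
        return round_half_up(self.total_correct)


def classification_table_metrics(counts) -> ClassificationTable:
    """Wrap 2x2 true x predicted counts and validate that summaries exist."""
    table = counts if isinstance(counts, ClassificationTable) else ClassificationTable.from_counts(
        counts.counts if isinstance(counts, ClassificationTable) else counts
    )
    table.per_class_correct  # raises on an empty true class
    return table


def confusion_at_threshold(probabilities, labels, threshold: float = 0.5):
    """TPR/FPR and the 2x2 table of predicted-low-EF calls at a cutoff.

    A sample is called positive (predicted low EF) when its probability is
    >= ``threshold``.  TPR is computed over true low-EF samples and FPR over
    true high-EF samples; both are returned as percentages.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pred_low = p >= threshold
    tp = int(np.sum(pred_low & y))
    fn = int(np.sum(~pred_low & y))
    fp = int(np.sum(pred_low & ~y))
    tn = int(np.sum(~pred_low & ~y))
    tpr = 100.0 * tp / (tp + fn)
    fpr = 100.0 * fp / (fp + tn)
    table = ClassificationTable.from_counts([[tn, fp], [fn, tp]])
    return tpr, fpr, table
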