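"""Differential expression between low-EF and high-EF patients.

Three call paths are exposed: a plain fold-change filter (the default call
used downstream), a SAM-style permutation d-statistic with an FDR-like
q-value per gene, and a signal-to-noise top-k ranking.  A fourth operation
intersects differential calls with an annotation gene set (e.g. angiogenesis).

All fold changes are geometric: the per-class means are taken on the log2
scale and ``fold_change = 2**(mean_low - mean_high)``, so values > 1 mean
up-regulation in the low-EF (dysfunction) group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

_EPS = 1e-8  # variance floor guarding constant genes

UP_IN_LOW = "up-in-low"
UP_IN_HIGH = "up-in-high"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (one GMT record)."""

    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in self.genes


def _class_masks(expr: pd.DataFrame, samples: pd.DataFrame):
    if "ef_class" not in samples.columns:
        raise ValueError("sample table must carry an 'ef_class' column")
    classes = samples.loc[expr.columns, "ef_class"]
    low = (classes == "low").to_numpy()
    high = (classes == "high").to_numpy()
    if not low.any() or not high.any():
        raise ValueError("both EF classes must be present")
    return low, high


def fold_change_filter(expr: pd.DataFrame, samples: pd.DataFrame, threshold: float = 1.3) -> pd.DataFrame:
    """Per-gene geometric fold change between classes with a symmetric cutoff.

    A gene passes when its fold change is >= ``threshold`` or <= 1/threshold.
    Genes with no non-missing value in one class are flagged ``evaluable=False``
    and never pass.  Returns a DataFrame indexed by gene with columns
    ``fold_change``, ``log2_diff``, ``direction``, ``passes_fc``, ``evaluable``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    low, high = _class_masks(expr, samples)
    x = expr.to_numpy(dtype=float)
    n_low = np.isfinite(x[:, low]).sum(axis=1)
    n_high = np.isfinite(x[:, high]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_low = np.nansum(x[:, low], axis=1) / n_low
        m_high = np.nansum(x[:, high], axis=1) / n_high
    evaluable = (n_low > 0) & (n_high > 0)
    diff = np.where(evaluable, m_low - m_high, np.nan)
    fc = np.power(2.0, diff)
    passes = np.zeros(len(fc), dtype=bool)
    with np.errstate(invalid="ignore"):
        passes[evaluable] = (fc[evaluable] >= threshold) | (fc[evaluable] <= 1.0 / threshold)
    direction = np.where(diff >= 0, UP_IN_LOW, UP_IN_HIGH)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_diff": diff,
            "direction": np.where(evaluable, direction, None),
            "passes_fc": passes,
            "evaluable": evaluable,
        },
        index=expr.index,
    )
    out.attrs["threshold"] = threshold
    return out


def _permutation_matrix(n: int, n_low: int, n_permutations: int, rng: np.random.Generator):
    """0/1 matrix (n x P) marking which samples play the low class per permutation.

    Enumerates every distinct split when there are at most ``n_permutations``
    of them, otherwise samples that many distinct splits without replacement.
    """
    total = comb(n, n_low)
    if total <= n_permutations:
        combos = list(itertools.combinations(range(n), n_low))
        exhaustive = True
    else:
        seen = set()
        combos = []
        while len(combos) < n_permutations:
            pick = tuple(sorted(rng.choice(n, size=n_low, replace=False).tolist()))
            if pick not in seen:
                seen.add(pick)
                combos.append(pick)
        exhaustive = False
    P = np.zeros((n, len(combos)))
    for j, idx in enumerate(combos):
        P[list(idx), j] = 1.0
    return P, exhaustive


def _group_stats(x0, x2, m, P):
    """Vectorized per-permutation group means and pooled standard errors."""
    n1 = m @ P
    n2 = m @ (1.0 - P)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = (x0 @ P) / n1
        mean2 = (x0 @ (1.0 - P)) / n2
        ss1 = (x2 @ P) - n1 * mean1**2
        ss2 = (x2 @ (1.0 - P)) - n2 * mean2**2
        dof = n1 + n2 - 2.0
        pooled = (ss1 + ss2) / dof * (1.0 / n1 + 1.0 / n2)
    bad = (n1 < 2) | (n2 < 2)
    pooled = np.where(bad, np.nan, np.clip(pooled, 0.0, None))
    return mean1 - mean2, np.sqrt(pooled)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability constant by the standard percentile search.

    Scans candidate s0 values at the 0..100th percentiles (steps of 5) of the
    gene standard errors and picks the one minimizing the coefficient of
    variation of the median absolute deviation of d across windows of s.
    Falls back to the median of s when there are too few genes to window.
    """
    ok = np.isfinite(r) & np.isfinite(s)
    r, s = r[ok], s[ok]
    if len(s) < 100:
        return float(np.median(s)) if len(s) else 0.0
    n_windows = int(min(100, max(10, len(s) // 50)))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    candidates = np.quantile(s, np.arange(0.0, 1.01, 0.05))
    best, best_cv = float(np.median(s)), np.inf
    for s0 in candidates:
        d = r / (s + s0 + _EPS)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]) / 0.64
        mu = mads.mean()
        if mu <= 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv - 1e-12:
            best_cv, best = cv, float(s0)
    return best


def sam_two_class(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Two-class unpaired SAM: moderated d-statistic with permutation FDR.

    ``d_i = (mean_low - mean_high) / (s_i + s0)`` with ``s_i`` the pooled
    standard error of the mean difference and ``s0`` the exchangeability
    constant chosen by percentile search over the observed statistics.  The
    null distribution pools the d-statistics of class-label permutations
    (all distinct splits when few enough, else a seeded sample).  Per gene:

    * ``p_value`` — fraction of permutations with ``|d*| >= |d|`` for that gene;
    * ``q_value`` — median-based FDR: median over permutations of the pooled
      count of ``|d*|`` beyond the gene's ``|d|``, divided by the observed
      count, clipped to [0, 1] and made monotone in ``|d|``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    low, high = _class_masks(expr, samples)
    if low.sum() < 2 or high.sum() < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)

    x = expr.to_numpy(dtype=float)
    finite = np.isfinite(x)
    x0 = np.where(finite, x, 0.0)
    x2 = x0**2
    m = finite.astype(float)

    obs_p = low.astype(float)[:, None]
    r_obs, s_obs = _group_stats(x0, x2, m, obs_p)
    r_obs, s_obs = r_obs[:, 0], s_obs[:, 0]
    s0 = _choose_s0(r_obs, s_obs)
    d_obs = r_obs / (s_obs + s0 + _EPS)

    P, exhaustive = _permutation_matrix(x.shape[1], int(low.sum()), n_permutations, rng)
    r_perm, s_perm = _group_stats(x0, x2, m, P)
    d_perm = r_perm / (s_perm + s0 + _EPS)

    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm)
    n_perm = P.shape[1]

    # per-gene permutation p-value
    with np.errstate(invalid="ignore"):
        p_val = np.nansum(abs_perm >= abs_obs[:, None] - 1e-12, axis=1) / n_perm
    p_val = np.where(np.isfinite(abs_obs), p_val, np.nan)

    # pooled median FDR
    finite_obs = np.isfinite(abs_obs)
    q_val = np.full(len(abs_obs), np.nan)
    if finite_obs.any():
        thresholds = abs_obs[finite_obs]
        counts = np.empty((n_perm, len(thresholds)))
        for j in range(n_perm):
            col = np.sort(abs_perm[np.isfinite(abs_perm[:, j]), j])
            counts[j] = len(col) - np.searchsorted(col, thresholds - 1e-12, side="left")
        v = np.median(counts, axis=0)
        obs_sorted = np.sort(thresholds)
        r_count = len(obs_sorted) - np.searchsorted(obs_sorted, thresholds - 1e-12, side="left")
        q = np.clip(v / np.maximum(r_count, 1), 0.0, 1.0)
        # enforce monotonicity: more extreme |d| never has a larger q
        order = np.argsort(-thresholds, kind="stable")
        q_sorted = q[order]
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q[order] = q_sorted
        q_val[finite_obs] = q

    out = pd.DataFrame(
        {"d": d_obs, "s": s_obs, "p_value": p_val, "q_value": q_val},
        index=expr.index,
    )
    out.attrs.update({"s0": s0, "n_permutations": n_perm, "exhaustive": exhaustive})
    return out


def rank_top_genes(expr: pd.DataFrame, samples: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Top-k genes by absolute signal-to-noise ratio between the classes.

    ``s2n = (mean_low - mean_high) / (sd_low + sd_high)`` with a small variance
    floor; ties are broken lexicographically by gene id so the ranking is
    deterministic.  The sign of s2n gives the associated class.
    """
    if k > expr.shape[0]:
        raise ValueError("k exceeds the number of genes")
    low, high = _class_masks(expr, samples)
    x = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        m_low = np.nanmean(x[:, low], axis=1)
        m_high = np.nanmean(x[:, high], axis=1)
        sd_low = np.nanstd(x[:, low], axis=1, ddof=1)
        sd_high = np.nanstd(x[:, high], axis=1, ddof=1)
    s2n = (m_low - m_high) / (sd_low + sd_high + _EPS)
    df = pd.DataFrame(
        {
            "s2n": s2n,
            "abs_s2n": np.abs(s2n),
            "direction": np.where(s2n >= 0, UP_IN_LOW, UP_IN_HIGH),
        },
        index=expr.index,
    )
    df = df.dropna(subset=["s2n"])
    order = np.lexsort((df.index.to_numpy(), -df["abs_s2n"].to_numpy()))
    return df.iloc[order].head(k).drop(columns="abs_s2n")


def intersect_annotation(de: pd.DataFrame, gene_set: GeneSet):
    """Differential genes belonging to an annotation set, with direction counts.

    ``de`` is the output of :func:`fold_change_filter` (or any frame with
    ``passes_fc`` and ``direction`` columns).  Returns ``(subset, counts)``
    where counts is ``(n_up_in_low, n_up_in_high)``.
    """
    called = de[de["passes_fc"].astype(bool)] if "passes_fc" in de.columns else de
    subset = called[called.index.isin(gene_set.genes)]
    n_up_low = int((subset["direction"] == UP_IN_LOW).sum())
    n_up_high = int((subset["direction"] == UP_IN_HIGH).sum())
    return subset, (n_up_low, n_up_high)
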