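"""Two-channel expression normalization and presence filtering.

The expression substrate is a genes x samples matrix of log2(sample/reference)
ratios with NaN marking missing spots.  Normalization removes the
intensity-dependent dye bias (lowess of M on A); the presence filters drop
genes that were not measured often enough, first across hybridization
replicates of one sample, then across patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


@dataclass(frozen=True)
class TwoChannelArray:
    """One hybridization: per-spot log ratio M and mean log intensity A.

    ``dye_swap`` marks arrays hybridized with exchanged fluorophores; their M
    values are negated before replicates are combined.
    """

    gene_ids: pd.Index
    M: np.ndarray
    A: np.ndarray
    dye_swap: bool = False

    def __post_init__(self):
        if len(self.gene_ids) != len(self.M) or len(self.M) != len(self.A):
            raise ValueError("gene_ids, M and A must have identical length")
        if self.gene_ids.has_duplicates:
            raise ValueError("gene identifiers must be unique")


def lowess_normalize(array: TwoChannelArray, span: float = 0.4, iterations: int = 3) -> TwoChannelArray:
    """Subtract a locally weighted regression of M on A (print-tip-free lowess).

    Parameters
    ----------
    span : fraction of spots in each local window (0 < span <= 1).
    iterations : robustness iterations down-weighting outlier spots.

    Returns a new array with ``M - f(A)``; missing spots stay missing.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    mask = np.isfinite(array.M) & np.isfinite(array.A)
    if mask.sum() < 10:
        raise ValueError("need at least 10 non-missing spots to fit the trend")
    fitted = _sm_lowess(
        array.M[mask], array.A[mask], frac=span, it=iterations,
        xvals=array.A[mask],
    )
    new_m = np.array(array.M, dtype=float)
    new_m[mask] = array.M[mask] - fitted
    return replace(array, M=new_m)


def replicate_presence_filter(
    replicate_arrays: list[TwoChannelArray],
    min_present: int = 3,
    total: int | None = None,
):
    """Keep genes measured on >= ``min_present`` of ``total`` replicate arrays.

    Dye-swap replicates are sign-corrected (M negated) before the retained
    genes' values are averaged into one combined column.

    Returns ``(kept_gene_ids, combined)`` where ``combined`` is a Series over
    the kept genes holding the mean of the non-missing sign-corrected M values.
    """
    if not replicate_arrays:
        raise ValueError("replicate list is empty")
    if total is None:
        total = len(replicate_arrays)
    if not 1 <= min_present <= total:
        raise ValueError("require total >= min_present >= 1")
    genes = replicate_arrays[0].gene_ids
    for arr in replicate_arrays[1:]:
        if not arr.gene_ids.equals(genes):
            raise ValueError("replicate arrays must share the same gene index")
    signed = np.vstack([(-arr.M if arr.dye_swap else arr.M) for arr in replicate_arrays])
    present = np.isfinite(signed)
    keep = present.sum(axis=0) >= min_present
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(present, signed, np.nan), axis=0)
    kept_ids = genes[keep]
    return set(kept_ids), pd.Series(means[keep], index=kept_ids)


def patient_presence_filter(expr: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Retain genes non-missing in at least ``ceil(min_fraction * n_samples)`` samples.

    The boundary is inclusive: with 32 patients and the default 0.5, a gene
    present in exactly 16 is kept.  Sample columns are never altered.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    needed = math.ceil(min_fraction * expr.shape[1])
    counts = expr.notna().sum(axis=1)
    return expr.loc[counts >= needed]
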