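"""Normalisation, outlier filtering, smoothing, and replicate consistency.

The processing order for a paired dataset is:

* RNA: natural-log transform -> quantile normalisation -> complete-case
  filter -> jackknife spikiness (TRV) filter (threshold 3) -> LOWESS.
* protein: sum-of-intensity normalisation excluding the top 5% of each
  column (on the natural scale) -> natural-log transform -> complete-case
  filter -> TRV filter (threshold 2) -> LOWESS.

The TRV ("total range of variation") filter deletes one point at a time
from a gene's series and records max - min of the remainder; the ratio
median(TRV)/min(TRV) measures how much a single point dominates the
range ("spikiness").  A gene whose series is flat except for one aberrant
point has a small min TRV and a large ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .containers import LOG, NATURAL, ConfigurationError, ExpressionMatrix

#: default spikiness thresholds per level
TRV_THRESHOLD_RNA = 3.0
TRV_THRESHOLD_PROTEIN = 2.0


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log; requires a natural-scale, positive matrix."""
    if matrix.scale != NATURAL:
        raise ConfigurationError("matrix already log scale")
    arr = matrix.values.to_numpy(dtype=float)
    bad = np.asarray((arr <= 0) & ~np.isnan(arr))
    if bad.any():
        g, t = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value for gene {matrix.values.index[g]!r} "
            f"at {matrix.time_grid[t]:g} h; cannot log-transform"
        )
    out = pd.DataFrame(np.log(arr), index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(out, scale=LOG)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to share the across-column mean sorted distribution.

    Ties within a column receive the mean of the reference values at the
    rank positions the tie group occupies.  Columns with missing values are
    normalised through their quantile function (linear interpolation);
    an all-missing column is an error.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ConfigurationError("quantile normalisation needs >= 2 columns")
    arr = df.to_numpy(dtype=float)
    if np.all(np.isnan(arr), axis=0).any():
        raise ValueError("column with all values missing")
    n = arr.shape[0]
    if not np.isnan(arr).any():
        reference = np.sort(arr, axis=0).mean(axis=1)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            order = np.argsort(col, kind="mergesort")
            assigned = np.empty(n)
            assigned[order] = reference
            # tie groups share the mean reference over their occupied ranks
            ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
            out[:, j] = ser.to_numpy()
    else:
        # quantile-function route tolerant of missing cells
        probs = np.linspace(0, 1, n)
        quantiles = np.column_stack(
            [np.quantile(arr[~np.isnan(arr[:, j]), j], probs) for j in range(arr.shape[1])]
        )
        reference = quantiles.mean(axis=1)
        out = np.full_like(arr, np.nan)
        for j in range(arr.shape[1]):
            mask = ~np.isnan(arr[:, j])
            col = arr[mask, j]
            m = col.size
            ranks = stats.rankdata(col, method="average")
            p = (ranks - 1) / (m - 1) if m > 1 else np.array([0.5])
            out[mask, j] = np.interp(p, probs, reference)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return matrix.copy_with(res)


def lfq_sum_normalize(matrix: ExpressionMatrix, top_fraction: float = 0.05) -> ExpressionMatrix:
    """Divide each column by its intensity sum excluding the largest values.

    ``ceil(top_fraction * n_genes)`` largest values of each column are left
    out of the normaliser so extremely abundant proteins do not dominate it.
    """
    if matrix.scale != NATURAL:
        raise ConfigurationError("sum normalisation applies to natural-scale intensities")
    df = matrix.values
    n_excl = int(np.ceil(top_fraction * df.shape[0]))
    out = {}
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        finite = np.sort(vals[~np.isnan(vals)])
        kept = finite[: finite.size - n_excl] if n_excl else finite
        normalizer = kept.sum()
        if normalizer <= 0:
            raise ValueError(f"non-positive normaliser in column {col!r}")
        out[col] = vals / normalizer
    res = pd.DataFrame(out, index=df.index)
    return matrix.copy_with(res)


def complete_case_filter(matrices: list[ExpressionMatrix]) -> list[str]:
    """Genes present with no missing value in every supplied matrix."""
    if not matrices:
        raise ConfigurationError("no matrices supplied")
    common: pd.Index | None = None
    for m in matrices:
        complete = m.values.index[m.values.notna().all(axis=1)]
        common = complete if common is None else common.intersection(complete)
    genes = list(common)
    if not genes:
        warnings.warn("complete-case filter left no genes", stacklevel=2)
    return genes


def trv_spikiness(series: np.ndarray) -> tuple[float, np.ndarray]:
    """Jackknife spikiness of one series: median(TRV) / min(TRV).

    ``TRV_j`` is max - min of the series with point ``j`` deleted.  A
    constant series (all TRV = 0) scores 1 by convention; a series whose
    range is carried entirely by one point (min TRV = 0, median > 0)
    scores +inf.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("spikiness needs >= 3 points")
    if np.isnan(y).any():
        raise ValueError("spikiness undefined with missing values")
    trv = np.array([np.ptp(np.delete(y, j)) for j in range(y.size)])
    med, mn = float(np.median(trv)), float(trv.min())
    if mn == 0.0:
        return (1.0, trv) if med == 0.0 else (np.inf, trv)
    return med / mn, trv


def trv_filter(
    matrix: ExpressionMatrix, threshold: float
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain genes with spikiness strictly below ``threshold``.

    Returns the filtered matrix and a per-gene report (jackknife TRVs,
    spikiness, retained flag).  Genes with missing values cannot be scored
    and are dropped (complete-case filtering is expected to run first).
    """
    rows = []
    retained_genes = []
    for gene, row in matrix.values.iterrows():
        y = row.to_numpy(dtype=float)
        if np.isnan(y).any():
            rows.append({"gene_id": gene, "spikiness": np.nan, "retained": False})
            continue
        spk, trv = trv_spikiness(y)
        keep = bool(spk < threshold)
        rec = {"gene_id": gene, "spikiness": spk, "retained": keep}
        rec.update({f"trv_{j}": v for j, v in enumerate(trv)})
        rows.append(rec)
        if keep:
            retained_genes.append(gene)
    report = pd.DataFrame(rows).set_index("gene_id")
    return matrix.copy_with(matrix.values.loc[retained_genes]), report


def lowess_smooth(
    series: np.ndarray,
    time_grid: np.ndarray,
    span: float = 2.0 / 3.0,
    iterations: int = 3,
) -> np.ndarray:
    """Robust locally weighted regression evaluated at the original hours.

    The x-axis is actual hours (the grid is strongly uneven: 0.5 h vs 8 h
    gaps), ``span`` is the fraction of points entering each local fit, and
    ``iterations`` robustifying reweights down-weight outliers.
    """
    y = np.asarray(series, dtype=float)
    x = np.asarray(time_grid, dtype=float)
    if y.size < 4:
        raise ValueError("smoothing needs >= 4 points")
    fitted = _sm_lowess(y, x, frac=span, it=iterations, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def lowess_smooth_matrix(
    matrix: ExpressionMatrix, span: float = 2.0 / 3.0, iterations: int = 3
) -> ExpressionMatrix:
    """Apply :func:`lowess_smooth` to every gene row."""
    grid = matrix.time_grid
    out = matrix.values.copy()
    sm = np.vstack(
        [lowess_smooth(row, grid, span, iterations) for row in matrix.values.to_numpy(dtype=float)]
    ) if len(out) else matrix.values.to_numpy(dtype=float)
    out.iloc[:, :] = sm
    return matrix.copy_with(out)


def rcm(series_rep1: np.ndarray, series_rep2: np.ndarray) -> tuple[float, float]:
    """Replicate consistency measure: Pearson r between replicate series.

    Returns (r, two-sided p-value) from the t transformation with n - 2
    degrees of freedom; with 8 time points r > 0.7 sits at p ~ 0.05.
    Zero variance in either series yields (nan, nan).
    """
    a = np.asarray(series_rep1, dtype=float)
    b = np.asarray(series_rep2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("replicate series must share length >= 3")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("replicate consistency undefined with missing values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
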