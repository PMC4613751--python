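"""Array- and feature-level QC, quantile normalization, and KNN imputation.

Expression matrices are pandas DataFrames with transcripts as rows and
samples as columns; values are log2 intensities and ``NaN`` marks missing
cells.  Feature-quality flags are carried as a pair of boolean DataFrames
aligned (or alignable) to the matrix: ``uniform`` (True = the feature was
uniform on that array) and ``negative_filtered`` (True = the feature failed
the negative-control intensity filter and must be discarded).

The intended pipeline order is fixed::

    qc_filter_arrays -> filter_features -> quantile_normalize -> impute_missing
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureFlags",
    "qc_filter_arrays",
    "filter_features",
    "quantile_normalize",
    "impute_missing",
]


@dataclass
class FeatureFlags:
    """Per-cell quality flags for an expression matrix.

    Parameters
    ----------
    uniform
        Boolean DataFrame (transcripts x samples); True where the feature
        was scored uniform. Cells absent from the frame default to True.
    negative_filtered
        Boolean DataFrame; True where the feature failed the negative
        filter. Cells absent default to False.
    """

    uniform: pd.DataFrame
    negative_filtered: pd.DataFrame

    def aligned_to(self, matrix: pd.DataFrame) -> "FeatureFlags":
        """Reindex both flag frames onto ``matrix``'s axes with defaults."""
        uni = (
            self.uniform.reindex(index=matrix.index, columns=matrix.columns)
            .fillna(True)
            .astype(bool)
        )
        neg = (
            self.negative_filtered.reindex(index=matrix.index, columns=matrix.columns)
            .fillna(False)
            .astype(bool)
        )
        return FeatureFlags(uniform=uni, negative_filtered=neg)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")


def qc_filter_arrays(
    matrix: pd.DataFrame,
    flags: FeatureFlags,
    max_nonuniform_frac: float = 0.03,
) -> pd.DataFrame:
    """Drop arrays (samples) whose non-uniform feature fraction exceeds the cap.

    An array is retained iff its fraction of non-uniform features is
    ``<= max_nonuniform_frac`` (the drop rule is strictly greater-than,
    so a fraction exactly at the cap survives).

    Raises
    ------
    ValueError
        If every array is dropped.
    """
    _check_matrix(matrix)
    flags = flags.aligned_to(matrix)
    nonuniform_frac = (~flags.uniform).mean(axis=0)
    keep = nonuniform_frac <= max_nonuniform_frac
    dropped = matrix.columns[~keep].tolist()
    if dropped:
        logger.info(
            "qc_filter_arrays: dropped %d/%d arrays (> %.1f%% non-uniform): %s",
            len(dropped), matrix.shape[1], 100 * max_nonuniform_frac, dropped,
        )
    if not keep.any():
        raise ValueError(
            f"all {matrix.shape[1]} arrays exceed the non-uniform threshold "
            f"of {max_nonuniform_frac:g}"
        )
    return matrix.loc[:, keep]


def filter_features(matrix: pd.DataFrame, flags: FeatureFlags) -> pd.DataFrame:
    """Mask negative-filtered cells and drop transcripts missing everywhere.

    Flagged cells become NaN; transcripts that end up missing in every
    retained sample are removed (count logged).
    """
    _check_matrix(matrix)
    flags = flags.aligned_to(matrix)
    out = matrix.mask(flags.negative_filtered)
    all_missing = out.isna().all(axis=1)
    if all_missing.any():
        logger.info(
            "filter_features: dropped %d transcripts missing in all samples",
            int(all_missing.sum()),
        )
    return out.loc[~all_missing]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples so their value distributions coincide.

    On complete data this is the classic sort / row-mean / unsort scheme:
    every column's sorted values become the cross-column mean of sorted
    values. Missing cells are allowed: the reference distribution is the
    mean of per-column quantile functions evaluated on a common grid, and
    each observed value is mapped through its (average) rank among the
    column's observed values, interpolating on the grid.  Ties receive the
    mean of the reference values they span.

    Raises
    ------
    ValueError
        If fewer than two samples are supplied.
    """
    _check_matrix(matrix)
    n_rows, n_cols = matrix.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if n_rows == 0:
        return matrix.copy()

    values = matrix.to_numpy(dtype=float)
    grid = np.linspace(0.0, 1.0, n_rows)
    # reference quantile function: mean over columns of each column's
    # empirical quantiles on the common grid
    col_quantiles = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        obs = values[~np.isnan(values[:, j]), j]
        if obs.size == 0:
            raise ValueError(f"sample {matrix.columns[j]!r} has no observed values")
        col_quantiles[:, j] = np.quantile(obs, grid)
    reference = col_quantiles.mean(axis=1)

    out = np.full_like(values, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(values[:, j])
        obs = values[mask, j]
        n_obs = obs.size
        if n_obs == 1:
            out[mask, j] = reference.mean()
            continue
        # average ranks handle ties; map rank r (1..n_obs) to p=(r-1)/(n_obs-1)
        p = (rankdata(obs, method="average") - 1.0) / (n_obs - 1.0)
        out[mask, j] = np.interp(p, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_missing(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """KNN-impute missing cells from the nearest transcripts.

    For each missing cell (transcript t, sample s), the k transcripts
    closest to t — Euclidean distance over co-observed samples, normalized
    by the number of co-observed samples, ties broken by row order — among
    those with an observed value in sample s contribute the mean of their
    values in s. Observed cells are never altered.

    Raises
    ------
    ValueError
        If k < 1 or any transcript has no observed value at all.
    """
    _check_matrix(matrix)
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float)
    missing = np.isnan(values)
    fully_missing = missing.all(axis=1)
    if fully_missing.any():
        ids = matrix.index[fully_missing].tolist()
        raise ValueError(f"transcripts with no observed values: {ids[:10]}")
    if not missing.any():
        return matrix.copy()

    out = values.copy()
    rows_todo = np.flatnonzero(missing.any(axis=1))
    obs = ~missing
    for i in rows_todo:
        # mean squared difference over co-observed samples, against all rows
        diff = values[i] - values          # (n_rows, n_cols), NaN where either missing
        sq = np.square(diff)
        co = obs[i] & obs                  # co-observed mask
        n_co = co.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dist = np.where(n_co > 0, np.nansum(np.where(co, sq, 0.0), axis=1) / np.maximum(n_co, 1), np.inf)
        dist[i] = np.inf                   # never self
        for j in np.flatnonzero(missing[i]):
            candidates = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if candidates.size == 0:
                raise ValueError(
                    f"no neighbour with an observed value in sample "
                    f"{matrix.columns[j]!r} for transcript {matrix.index[i]!r}"
                )
            order = candidates[np.lexsort((candidates, dist[candidates]))]
            nearest = order[: min(k, order.size)]
            out[i, j] = values[nearest, j].mean()
    n_imputed = int(missing.sum())
    logger.info("impute_missing: imputed %d cells with k=%d", n_imputed, k)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
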