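"""Per-transcript two-way fixed-effects ANOVA with BH multiple-testing control.

Each transcript is fitted with the additive linear model
``expression ~ sex + progeny`` (no interaction) by least squares; factor
F statistics use type-II sums of squares, which tolerate the mild
sex-ratio imbalance between progenies and coincide with type-I on
balanced designs.  The progeny contrast is restricted to the two parental
populations by default (hybrids excluded).

All transcripts are fitted in one vectorized pass: the three projection
matrices (full, drop-sex, drop-progeny) are shared across transcripts, so
the per-transcript work is a handful of matrix products.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["two_way_anova", "bh_adjust", "select_by_threshold"]


def _design(meta: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Intercept + treatment dummies for the given factors."""
    cols = [np.ones(len(meta))]
    for f in factors:
        levels = sorted(meta[f].astype(str).unique())
        for level in levels[1:]:
            cols.append((meta[f].astype(str) == level).to_numpy(float))
    return np.column_stack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of y regressed on x."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return np.sum(resid * resid, axis=0)


def two_way_anova(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    progenies: tuple[str, ...] = ("FRA", "DAN"),
    sex_factor: str = "sex",
    progeny_factor: str = "progeny",
) -> pd.DataFrame:
    """Additive two-way ANOVA (sex, progeny) per transcript.

    Parameters
    ----------
    matrix
        Transcripts x samples expression matrix, complete (imputed).
    metadata
        Sample metadata indexed by sample id with the two factor columns.
    progenies
        Progeny levels entering the model; the default restricts the
        contrast to the two parental populations.

    Returns
    -------
    DataFrame indexed by transcript with columns ``F_sex``, ``p_sex``,
    ``padj_sex``, ``F_progeny``, ``p_progeny``, ``padj_progeny`` and a
    boolean ``constant`` flag.  Constant transcripts get NaN statistics.

    Raises
    ------
    ValueError
        If any sex x progeny cell has fewer than 2 samples.
    """
    meta = metadata.loc[metadata[progeny_factor].isin(progenies)]
    samples = [s for s in matrix.columns if s in meta.index]
    meta = meta.loc[samples]
    counts = meta.groupby([sex_factor, progeny_factor], observed=True).size()
    expected_cells = len(meta[sex_factor].unique()) * len(progenies)
    if len(counts) < expected_cells or (counts < 2).any():
        bad = counts[counts < 2].index.tolist() if len(counts) else "all"
        raise ValueError(f"each sex x progeny cell needs >= 2 samples; deficient: {bad}")

    y = matrix[samples].to_numpy(dtype=float).T  # samples x transcripts
    x_full = _design(meta, [sex_factor, progeny_factor])
    x_nosex = _design(meta, [progeny_factor])
    x_noprog = _design(meta, [sex_factor])

    n = y.shape[0]
    df_sex = x_full.shape[1] - x_nosex.shape[1]
    df_prog = x_full.shape[1] - x_noprog.shape[1]
    df_resid = n - x_full.shape[1]

    rss_full = _rss(x_full, y)
    ss_sex = _rss(x_nosex, y) - rss_full
    ss_prog = _rss(x_noprog, y) - rss_full

    constant = np.isclose(y.var(axis=0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = rss_full / df_resid
        f_sex = (ss_sex / df_sex) / mse
        f_prog = (ss_prog / df_prog) / mse
    f_sex[constant] = np.nan
    f_prog[constant] = np.nan
    p_sex = stats.f.sf(f_sex, df_sex, df_resid)
    p_prog = stats.f.sf(f_prog, df_prog, df_resid)
    if constant.any():
        logger.info("two_way_anova: %d constant transcripts flagged", constant.sum())

    return pd.DataFrame(
        {
            "F_sex": f_sex,
            "p_sex": p_sex,
            "padj_sex": bh_adjust(p_sex),
            "F_progeny": f_prog,
            "p_progeny": p_prog,
            "padj_progeny": bh_adjust(p_prog),
            "constant": constant,
        },
        index=matrix.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Missing entries (NaN) are passed through untouched and do not count
    toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        obs = p[mask]
        if (obs < 0).any() or (obs > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(obs, method="fdr_bh")[1]
    return out


def select_by_threshold(
    table: pd.DataFrame, factor: str, cutoff: float = 1e-4
) -> list:
    """Transcripts with adjusted p below the cutoff for one factor, by padj."""
    col = f"padj_{factor}"
    if col not in table.columns:
        raise KeyError(f"unknown factor {factor!r}; table has {list(table.columns)}")
    hits = table.loc[table[col] < cutoff, col].sort_values(kind="mergesort")
    return hits.index.tolist()
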