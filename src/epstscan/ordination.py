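"""Redundancy analysis (RDA), variance partitioning and axis-contribution tails.

RDA is the principal-component decomposition of the fitted values from a
multivariate least-squares regression of a (samples x transcripts) response
matrix on a factor design matrix.  Partial RDA first residualizes both the
responses and the predictors on a conditioning design.  Variance
partitioning runs the full two-factor model plus the two partial models and
reports each factor's share of the explained (constrained) variance.

Per-transcript "contributions" to a constrained axis are the transcript
loadings (right singular vectors) on that axis; extreme loadings on the
second axis flag the transcripts driving between-population separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "VariancePartition",
    "design_matrix",
    "rda_fit",
    "variance_partition",
    "contribution_tails",
    "cluster_transcripts",
]

_SINGULAR_TOL = 1e-9


@dataclass
class OrdinationResult:
    """Constrained-ordination fit.

    Attributes
    ----------
    axis_eigenvalues
        Variance explained by each constrained axis (squared singular
        values of the fitted matrix divided by n - 1), descending.
    total_variance
        Total variance of the (conditioned, centered) responses.
    constrained_fraction
        sum(axis_eigenvalues) / total_variance.
    sample_scores
        Samples x axes matrix of site scores (U * s).
    transcript_contributions
        Transcripts x axes matrix of loadings (right singular vectors).
    model_label
        Human-readable model description, e.g. ``"Sex+Progeny"``.
    """

    axis_eigenvalues: np.ndarray
    total_variance: float
    constrained_fraction: float
    sample_scores: pd.DataFrame
    transcript_contributions: pd.DataFrame
    model_label: str = ""


@dataclass
class VariancePartition:
    """Shares of the explained variance attributable to each factor."""

    sex_fraction_of_explained: float
    progeny_fraction_of_explained: float
    full: OrdinationResult = field(repr=False, default=None)
    sex_partial: OrdinationResult = field(repr=False, default=None)
    progeny_partial: OrdinationResult = field(repr=False, default=None)


def design_matrix(metadata: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Treatment-coded dummy design for the requested metadata factors.

    The reference level is the alphabetically first level of each factor and
    is dropped; no intercept column is produced (responses and predictors
    are centered downstream). Columns are named ``factor:level``.
    """
    if not factors:
        return pd.DataFrame(index=metadata.index)
    cols: dict[str, np.ndarray] = {}
    for factor in factors:
        if factor not in metadata.columns:
            raise KeyError(f"unknown factor {factor!r}; have {list(metadata.columns)}")
        series = metadata[factor]
        if series.isna().any():
            bad = metadata.index[series.isna()].tolist()
            raise ValueError(f"factor {factor!r} missing for samples {bad[:5]}")
        levels = sorted(series.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} has a single level {levels!r}")
        for level in levels[1:]:
            cols[f"{factor}:{level}"] = (series.astype(str) == level).to_numpy(float)
    return pd.DataFrame(cols, index=metadata.index)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _residualize(a: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of (centered) ``a`` after least-squares projection onto ``z``."""
    coef, *_ = np.linalg.lstsq(z, a, rcond=None)
    return a - z @ coef


def rda_fit(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    Z: pd.DataFrame | None = None,
    model_label: str = "",
) -> OrdinationResult:
    """Fit a (partial) redundancy analysis of responses Y on design X.

    Parameters
    ----------
    Y
        Samples x transcripts response matrix (no missing values).
    X
        Samples x predictors design matrix (e.g. from :func:`design_matrix`).
    Z
        Optional conditioning design; when given, both Y and X are replaced
        by their residuals on Z before the constrained fit (partial RDA).

    Notes
    -----
    Y is column-centered (no transcript-wise scaling).  Constrained axes
    are the singular directions of the fitted values ``X @ B`` with
    ``B`` the least-squares coefficients; eigenvalues are squared singular
    values divided by ``n - 1``.
    """
    if list(Y.index) != list(X.index):
        raise ValueError("Y and X must be indexed by the same samples in the same order")
    n = Y.shape[0]
    y = _center(Y.to_numpy(dtype=float))
    x = _center(X.to_numpy(dtype=float))
    if Z is not None and Z.shape[1] > 0:
        if list(Z.index) != list(Y.index):
            raise ValueError("Z must be indexed by the same samples as Y")
        z = _center(Z.to_numpy(dtype=float))
        y = _residualize(y, z)
        x = _residualize(x, z)
        n_cond = np.linalg.matrix_rank(z)
    else:
        n_cond = 0
    if n <= x.shape[1] + n_cond + 1:
        raise ValueError(
            f"need more samples ({n}) than predictor plus conditioning "
            f"columns ({x.shape[1] + n_cond}) for RDA"
        )

    total_variance = float(np.sum(y * y) / (n - 1))
    if x.shape[1] == 0:
        fitted = np.zeros_like(y)
    else:
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            names = list(X.columns)
            raise ValueError(
                f"design is rank-deficient after conditioning (rank {rank} < "
                f"{x.shape[1]} columns): {names}"
            )
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ coef

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    scale = s[0] if s.size and s[0] > 0 else 1.0
    n_axes = int(np.sum(s > _SINGULAR_TOL * scale))
    n_axes = min(n_axes, x.shape[1]) if x.shape[1] else 0
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eigenvalues = s**2 / (n - 1)
    constrained = float(eigenvalues.sum() / total_variance) if total_variance > 0 else 0.0

    axis_names = [f"RDA{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        axis_eigenvalues=eigenvalues,
        total_variance=total_variance,
        constrained_fraction=constrained,
        sample_scores=pd.DataFrame(u * s, index=Y.index, columns=axis_names),
        transcript_contributions=pd.DataFrame(vt.T, index=Y.columns, columns=axis_names),
        model_label=model_label,
    )


def variance_partition(
    Y: pd.DataFrame,
    metadata: pd.DataFrame,
    sex_factor: str = "sex",
    progeny_factor: str = "progeny",
) -> VariancePartition:
    """Partition explained expression variance between sex and progeny.

    Fits the full model (Sex+Progeny) and the two partial models
    (Sex | Progeny and Progeny | Sex); each factor's share is the
    constrained variance of its partial model divided by the constrained
    variance of the full model.
    """
    meta = metadata.loc[Y.index]
    x_sex = design_matrix(meta, [sex_factor])
    x_prog = design_matrix(meta, [progeny_factor])
    x_full = pd.concat([x_sex, x_prog], axis=1)

    full = rda_fit(Y, x_full, model_label="Sex+Progeny")
    sex_part = rda_fit(Y, x_sex, Z=x_prog, model_label="Sex+Condition(Progeny)")
    prog_part = rda_fit(Y, x_prog, Z=x_sex, model_label="Progeny+Condition(Sex)")

    explained_full = float(full.axis_eigenvalues.sum())
    if explained_full <= 0:
        raise ValueError("full model explains no variance; partition undefined")
    return VariancePartition(
        sex_fraction_of_explained=float(sex_part.axis_eigenvalues.sum()) / explained_full,
        progeny_fraction_of_explained=float(prog_part.axis_eigenvalues.sum()) / explained_full,
        full=full,
        sex_partial=sex_part,
        progeny_partial=prog_part,
    )


def contribution_tails(
    contributions: pd.Series,
    lower_q: float = 0.001,
    upper_q: float = 0.999,
) -> list:
    """Transcripts in the nearest-rank tails of one axis' contribution scores.

    Returns the ``ceil(lower_q * n)`` smallest plus the
    ``ceil((1 - upper_q) * n)`` largest scores' transcript ids, ordered by
    score ascending.  With 31,918 distinct scores and the default 0.001 /
    0.999 quantiles this yields 32 + 32 = 64 transcripts.
    """
    scores = contributions.astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("contribution scores must be finite")
    n = len(scores)
    if n == 0:
        return []
    if scores.nunique() == 1:
        raise ValueError("all contribution scores identical; tails undefined")
    if scores.duplicated().any():
        logger.warning("contribution_tails: tied scores present; rank order by id")
    # epsilon guards against float slop (0.001 * 1000 = 1.0000000000000002)
    n_low = int(np.ceil(lower_q * n - 1e-9))
    n_high = int(np.ceil((1.0 - upper_q) * n - 1e-9))
    order = scores.sort_values(kind="mergesort")
    selected = pd.concat([order.iloc[:n_low], order.iloc[n - n_high:]])
    return selected.index.tolist()


def cluster_transcripts(matrix: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Ward-linkage clustering of transcripts on 1 - Pearson correlation.

    ``matrix`` is transcripts x samples, restricted to the transcripts of
    interest.  The agglomerative tree is cut into ``n_clusters`` labels
    (integers starting at 1).
    """
    if matrix.shape[0] < n_clusters:
        raise ValueError(
            f"need at least n_clusters={n_clusters} transcripts, got {matrix.shape[0]}"
        )
    values = matrix.to_numpy(dtype=float)
    if np.isclose(values.std(axis=1), 0.0).any():
        bad = matrix.index[np.isclose(values.std(axis=1), 0.0)].tolist()
        raise ValueError(f"constant transcript rows (correlation undefined): {bad[:5]}")
    if matrix.shape[0] == 1 or n_clusters == 1:
        return pd.Series(np.ones(matrix.shape[0], dtype=int), index=matrix.index)
    corr = np.corrcoef(values)
    dissim = 1.0 - corr
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dissim, checks=False), method="ward")
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")
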