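"""Mid-parent additivity filtering, eP_ST estimation, and the permutation scan.

eP_ST is the expression analogue of the quantitative-trait differentiation
index Q_ST::

    eP_ST = sigma2_GB / (sigma2_GB + 2 * sigma2_GW)

where ``sigma2_GB`` is the among-population and ``sigma2_GW`` the
within-population variance component of a transcript's expression,
estimated from a one-way ANOVA on the two parental populations by the
method of moments.  Under neutrality eP_ST is expected to be comparable to
marker F_ST; transcripts whose observed eP_ST exceeds the upper tail of a
permutation null (population labels shuffled) are called outliers.

Before the scan, transcripts are filtered for additive inheritance: a
hybrid progeny's mean must be statistically indistinguishable from the
mid-parent level (average of the two parental means).  Only additive
transcripts carry the between-population signal interpretable as heritable
differentiation.  Because expression differs massively between sexes in
gonad tissue, the whole procedure is run separately per sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AdditivityRecord",
    "VarianceComponents",
    "EpstRecord",
    "midparent_additivity_test",
    "additivity_table",
    "variance_components",
    "epst",
    "permutation_scan",
    "common_candidates",
    "additive_share",
]


@dataclass
class AdditivityRecord:
    transcript_id: object
    sex: str
    midparent_mean: float
    t_statistic: float
    p_value: float
    additive: bool


@dataclass
class VarianceComponents:
    """Among- (GB) and within- (GW) population variance components.

    Negative moment estimates of sigma2_GB are clipped to zero (clip
    logged by the caller); both components are always >= 0.
    """

    sigma2_GB: float
    sigma2_GW: float


@dataclass
class EpstRecord:
    transcript_id: object
    sex: str
    components: VarianceComponents
    epst: float
    null_quantile: float
    outlier: bool


def _contrast_stats(
    fra: np.ndarray, dan: np.ndarray, hyb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized linear-contrast t-test of hybrid mean vs mid-parent.

    Each input is (n_samples, n_transcripts).  Returns (midparent, t, p, df).
    """
    n_f, n_d, n_h = fra.shape[0], dan.shape[0], hyb.shape[0]
    for name, n in (("FRA", n_f), ("DAN", n_d), ("HYB", n_h)):
        if n < 2:
            raise ValueError(f"group {name} needs >= 2 values, got {n}")
    midparent = (fra.mean(axis=0) + dan.mean(axis=0)) / 2.0
    contrast = hyb.mean(axis=0) - midparent
    df = n_f + n_d + n_h - 3
    pooled_ss = (
        fra.var(axis=0, ddof=1) * (n_f - 1)
        + dan.var(axis=0, ddof=1) * (n_d - 1)
        + hyb.var(axis=0, ddof=1) * (n_h - 1)
    )
    pooled_var = pooled_ss / df
    se = np.sqrt(pooled_var * (1.0 / n_h + 1.0 / (4 * n_f) + 1.0 / (4 * n_d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / se
    # zero pooled variance: zero contrast -> t = 0 (additive); else infinite t
    zero_se = se == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (contrast == 0), 0.0, t)
        t = np.where(zero_se & (contrast != 0), np.sign(contrast) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return midparent, t, p, df


def midparent_additivity_test(
    values_fra,
    values_dan,
    values_hyb,
    alpha: float = 0.01,
    transcript_id=None,
    sex: str = "",
) -> AdditivityRecord:
    """Test whether hybrid expression sits at the theoretical mid-parent level.

    A pooled-variance linear contrast ``mu_HYB - (mu_FRA + mu_DAN)/2`` with
    ``df = n_total - 3``; the transcript is called additive when the test
    fails to reject at ``alpha`` (p >= alpha).  The pooled contrast (rather
    than a one-sample t against a constant) respects the sampling error of
    the estimated parental means.
    """
    fra = np.asarray(values_fra, dtype=float)[:, None]
    dan = np.asarray(values_dan, dtype=float)[:, None]
    hyb = np.asarray(values_hyb, dtype=float)[:, None]
    midparent, t, p, _ = _contrast_stats(fra, dan, hyb)
    return AdditivityRecord(
        transcript_id=transcript_id,
        sex=sex,
        midparent_mean=float(midparent[0]),
        t_statistic=float(t[0]),
        p_value=float(p[0]),
        additive=bool(p[0] >= alpha),
    )


def additivity_table(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.01,
    sex: str = "",
    progeny_factor: str = "progeny",
) -> pd.DataFrame:
    """Vectorized mid-parent additivity test for every transcript.

    ``matrix`` is transcripts x samples; ``metadata`` assigns each sample a
    progeny in {FRA, DAN, HYB}.  Returns a DataFrame indexed by transcript
    with columns midparent_mean, t_statistic, p_value, additive.
    """
    groups = {}
    for progeny in ("FRA", "DAN", "HYB"):
        ids = metadata.index[metadata[progeny_factor] == progeny]
        ids = [s for s in matrix.columns if s in set(ids)]
        groups[progeny] = matrix[ids].to_numpy(dtype=float).T
    midparent, t, p, _ = _contrast_stats(groups["FRA"], groups["DAN"], groups["HYB"])
    return pd.DataFrame(
        {
            "midparent_mean": midparent,
            "t_statistic": t,
            "p_value": p,
            "additive": p >= alpha,
        },
        index=matrix.index,
    )


def _n0(sizes: np.ndarray) -> float:
    """Effective per-group size for the unbalanced moment estimator."""
    n_total = sizes.sum()
    k = len(sizes)
    return (n_total - (sizes**2).sum() / n_total) / (k - 1)


def variance_components(values_fra, values_dan) -> VarianceComponents:
    """Method-of-moments variance components from a one-way two-group ANOVA.

    ``sigma2_GW`` is the within-group mean square; ``sigma2_GB`` is
    ``max(0, (MS_between - MS_within) / n0)`` with ``n0`` the
    harmonic-mean-adjusted per-group size.
    """
    groups = [np.asarray(values_fra, dtype=float), np.asarray(values_dan, dtype=float)]
    sizes = np.array([g.size for g in groups])
    if (sizes < 2).any():
        raise ValueError(f"each population needs >= 2 values, got sizes {sizes.tolist()}")
    n_total = int(sizes.sum())
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups))
    ms_within = ss_within / (n_total - k)
    ms_between = ss_between / (k - 1)
    gb = (ms_between - ms_within) / _n0(sizes)
    if gb < 0:
        logger.debug("variance_components: clipped negative sigma2_GB %.4g to 0", gb)
    return VarianceComponents(sigma2_GB=max(0.0, float(gb)), sigma2_GW=float(ms_within))


def epst(components: VarianceComponents) -> float:
    """eP_ST = sigma2_GB / (sigma2_GB + 2 sigma2_GW); 0 when both are 0."""
    denom = components.sigma2_GB + 2.0 * components.sigma2_GW
    if denom == 0.0:
        return 0.0
    return components.sigma2_GB / denom


def _epst_matrix(values: np.ndarray, is_first: np.ndarray) -> np.ndarray:
    """eP_ST for every row of a (transcripts x samples) matrix.

    ``is_first`` is the boolean population assignment of the columns.
    Returns one eP_ST per transcript; negative GB estimates clip to 0.
    """
    n1 = int(is_first.sum())
    n2 = int((~is_first).sum())
    g1 = values[:, is_first]
    g2 = values[:, ~is_first]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ss_within = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    ss_between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ms_within = ss_within / (n1 + n2 - 2)
    ms_between = ss_between / 1.0
    n0 = _n0(np.array([n1, n2]))
    gb = np.maximum(0.0, (ms_between - ms_within) / n0)
    denom = gb + 2.0 * ms_within
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, gb / denom, 0.0)
    return out


def permutation_scan(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    sex: str,
    alpha_add: float = 0.01,
    n_perm: int = 5000,
    outlier_q: float = 0.999,
    seed: int | None = None,
    sex_factor: str = "sex",
    progeny_factor: str = "progeny",
    return_null: bool = False,
):
    """Per-sex additivity-filtered eP_ST outlier scan.

    Procedure: (1) restrict to samples of the given sex; (2) keep
    transcripts whose hybrid mean passes the mid-parent additivity test at
    ``alpha_add``; (3) compute observed eP_ST per kept transcript from the
    FRA/DAN samples; (4) for each of ``n_perm`` permutations shuffle the
    FRA/DAN population labels and recompute eP_ST for every kept
    transcript; (5) the null threshold is the ``outlier_q`` empirical
    quantile of the pooled permuted values (one global threshold per sex);
    (6) a transcript is an outlier iff its observed eP_ST strictly exceeds
    the threshold.

    The additivity filter is fixed before resampling (not recomputed inside
    permutations), and hybrids take no part in eP_ST or its null.

    Returns
    -------
    DataFrame indexed by the additive transcripts with columns sex,
    sigma2_GB, sigma2_GW, epst, null_quantile, outlier.  With
    ``return_null=True``, a ``(frame, pooled_null_values)`` tuple instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta_sex = metadata.loc[metadata[sex_factor] == sex]
    if meta_sex.empty:
        raise ValueError(f"no samples of sex {sex!r}")
    cols = [s for s in matrix.columns if s in set(meta_sex.index)]
    sub = matrix[cols]
    meta_sex = meta_sex.loc[cols]
    for progeny in ("FRA", "DAN", "HYB"):
        if (meta_sex[progeny_factor] == progeny).sum() < 2:
            raise ValueError(f"sex {sex!r} has < 2 samples of progeny {progeny}")

    add = additivity_table(sub, meta_sex, alpha=alpha_add, sex=sex,
                           progeny_factor=progeny_factor)
    kept = add.index[add["additive"]]
    logger.info(
        "permutation_scan[%s]: %d/%d transcripts additive at alpha=%g",
        sex, len(kept), len(add), alpha_add,
    )
    if len(kept) == 0:
        logger.warning("permutation_scan[%s]: no additive transcripts", sex)
        empty = pd.DataFrame(
            columns=["sex", "sigma2_GB", "sigma2_GW", "epst", "null_quantile", "outlier"]
        )
        return (empty, np.empty(0)) if return_null else empty

    parental = meta_sex.index[meta_sex[progeny_factor].isin(("FRA", "DAN"))].tolist()
    values = sub.loc[kept, parental].to_numpy(dtype=float)
    is_fra = (meta_sex.loc[parental, progeny_factor] == "FRA").to_numpy()

    observed = _epst_matrix(values, is_fra)
    # components reported alongside (same estimator as the scan)
    comps = [
        variance_components(values[i, is_fra], values[i, ~is_fra])
        for i in range(values.shape[0])
    ]

    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    n_fra = int(is_fra.sum())
    null = np.empty((n_perm, values.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        labels = np.zeros(n_samples, dtype=bool)
        labels[perm[:n_fra]] = True
        null[b] = _epst_matrix(values, labels)
    threshold = float(np.quantile(null.ravel(), outlier_q))

    out = pd.DataFrame(
        {
            "sex": sex,
            "sigma2_GB": [c.sigma2_GB for c in comps],
            "sigma2_GW": [c.sigma2_GW for c in comps],
            "epst": observed,
            "null_quantile": threshold,
            "outlier": observed > threshold,
        },
        index=kept,
    )
    logger.info(
        "permutation_scan[%s]: threshold=%.4f, %d outliers of %d additive",
        sex, threshold, int(out["outlier"].sum()), len(out),
    )
    return (out, null.ravel()) if return_null else out


def common_candidates(*lists) -> list:
    """Intersection of >= 2 transcript id lists, ordered by the first list."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [t for t in lists[0] if t in common]


def additive_share(additive_counts, n_transcripts: int) -> float:
    """Combined share (percent) of the array's transcripts called additive.

    ``additive_counts`` holds the per-sex additive transcript counts; the
    share is their sum over the total number of transcripts on the array.
    """
    total = int(np.sum(additive_counts))
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    return 100.0 * total / n_transcripts
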