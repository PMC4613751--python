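"""Sex-ratio and condition-index statistics for the common-garden progenies.

The condition index (AFNOR) is ``100 * wet flesh weight / total weight``, a
ripeness / reproductive-effort proxy in oysters.  Sex-ratio is
``males / (males + females)``; values below 0.5 are female-biased.
Sex distributions are compared between progenies with Pearson chi-square
tests (no continuity correction), and the condition index with a two-way
fixed-effects ANOVA (sex, progeny) followed by Fisher's protected LSD
letters among progenies.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

logger = logging.getLogger(__name__)

__all__ = [
    "condition_index",
    "sex_counts",
    "sex_ratio_test",
    "SexRatioResult",
    "ci_anova",
    "CiAnovaResult",
]


def condition_index(wet_flesh_weight, total_weight) -> float:
    """AFNOR condition index: (wet flesh weight / total weight) x 100."""
    wet = np.asarray(wet_flesh_weight, dtype=float)
    total = np.asarray(total_weight, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_weight must be > 0")
    if np.any(wet < 0) or np.any(wet > total):
        raise ValueError("wet_flesh_weight must lie in [0, total_weight]")
    out = 100.0 * wet / total
    return float(out) if out.ndim == 0 else out


def sex_counts(records: pd.DataFrame, progeny_col: str = "progeny",
               sex_col: str = "sex") -> pd.DataFrame:
    """Per-progeny male/female counts and sex-ratio (males / total)."""
    tab = (
        records.groupby([progeny_col, sex_col], observed=True)
        .size()
        .unstack(sex_col, fill_value=0)
        .reindex(columns=["M", "F"], fill_value=0)
    )
    tab.columns = ["n_male", "n_female"]
    tab["sex_ratio"] = tab["n_male"] / (tab["n_male"] + tab["n_female"])
    return tab


@dataclass
class SexRatioResult:
    """Chi-square comparison(s) of sex distributions between progenies."""

    counts: pd.DataFrame
    omnibus_chi2: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: progeny_a, progeny_b, chi2, p


def sex_ratio_test(counts: pd.DataFrame, progenies: list[str] | None = None) -> SexRatioResult:
    """Pearson chi-square on the sex x progeny contingency table.

    Runs both the omnibus test over all requested progenies and every
    pairwise comparison, without continuity correction.

    Raises
    ------
    ValueError
        If any progeny has zero individuals, or a sex is absent everywhere.
    """
    if progenies is None:
        progenies = counts.index.tolist()
    tab = counts.loc[progenies, ["n_male", "n_female"]]
    if (tab.sum(axis=1) == 0).any():
        empty = tab.index[tab.sum(axis=1) == 0].tolist()
        raise ValueError(f"progenies with zero individuals: {empty}")
    if (tab.sum(axis=0) == 0).any():
        raise ValueError("a sex is absent from every progeny; table degenerate")

    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    rows = []
    for a, b in itertools.combinations(progenies, 2):
        sub = tab.loc[[a, b]].to_numpy()
        if (sub.sum(axis=0) == 0).any():
            c2, pv = np.nan, np.nan
        else:
            c2, pv, _, _ = stats.chi2_contingency(sub, correction=False)
        rows.append({"progeny_a": a, "progeny_b": b, "chi2": c2, "p": pv})
    return SexRatioResult(
        counts=counts.loc[progenies],
        omnibus_chi2=float(chi2),
        omnibus_p=float(p),
        pairwise=pd.DataFrame(rows),
    )


@dataclass
class CiAnovaResult:
    """Two-way ANOVA of condition index with diagnostics and LSD letters."""

    anova: pd.DataFrame
    shapiro_p: float
    bartlett_p: float
    letters: dict
    progeny_means: pd.Series
    pairwise_lsd: pd.DataFrame


def _letter_groups(means: pd.Series, not_different: set[frozenset]) -> dict:
    """Compact-letter display: shared letter = not significantly different."""
    order = means.sort_values(ascending=False).index.tolist()
    letters: dict = {g: "" for g in order}
    next_letter = iter(string.ascii_lowercase)
    assigned: list[set] = []  # one member set per letter
    for g in order:
        placed = False
        for members in assigned:
            if all(frozenset((g, other)) in not_different for other in members):
                members.add(g)
                placed = True
        if not placed:
            assigned.append({g})
    for members, letter in zip(assigned, next_letter):
        for g in members:
            letters[g] += letter
    return letters


def ci_anova(records: pd.DataFrame, alpha: float = 0.05,
             value_col: str = "condition_index") -> CiAnovaResult:
    """Two-way fixed-effects ANOVA of condition index plus protected LSD.

    Fits ``condition_index ~ sex + progeny`` (type-II sums of squares),
    reports Shapiro-Wilk normality of residuals and Bartlett homogeneity
    across sex x progeny groups as diagnostics, and — only when the progeny
    effect is significant at ``alpha`` (Fisher's protected LSD) — pairwise
    LSD comparisons among progenies summarized as letter groups.
    """
    cells = (
        records.groupby(["sex", "progeny"], observed=True)
        .size()
        .unstack("progeny", fill_value=0)
        .stack()
    )
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"each sex x progeny cell needs >= 2 records; deficient: {bad}")
    data = records.rename(columns={value_col: "ci"})

    if np.isclose(data["ci"].var(), 0.0):
        # degenerate constant response: F = 0, p = 1, single letter group
        anova = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0],
                "df": [1.0, data["progeny"].nunique() - 1.0, len(data) - 1.0
                       - data["progeny"].nunique()],
                "F": [0.0, 0.0, np.nan],
                "PR(>F)": [1.0, 1.0, np.nan],
            },
            index=["C(sex)", "C(progeny)", "Residual"],
        )
        means = data.groupby("progeny", observed=True)["ci"].mean()
        return CiAnovaResult(
            anova=anova, shapiro_p=1.0, bartlett_p=1.0,
            letters={g: "a" for g in means.index}, progeny_means=means,
            pairwise_lsd=pd.DataFrame(
                [{"progeny_a": a, "progeny_b": b, "t": np.nan, "p": np.nan}
                 for a, b in itertools.combinations(means.index, 2)]
            ),
        )

    model = ols("ci ~ C(sex) + C(progeny)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    resid = model.resid
    if np.isclose(resid.std(), 0.0):
        shapiro_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    groups = [g.to_numpy() for _, g in data.groupby(["sex", "progeny"], observed=True)["ci"]]
    if all(np.isclose(np.var(g), 0) for g in groups):
        bartlett_p = 1.0
    else:
        bartlett_p = float(stats.bartlett(*groups).pvalue)

    progeny_means = data.groupby("progeny", observed=True)["ci"].mean()
    sizes = data.groupby("progeny", observed=True)["ci"].size()
    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_resid = float(anova.loc["Residual", "df"])
    p_progeny = float(anova.loc["C(progeny)", "PR(>F)"])

    rows = []
    not_different: set[frozenset] = set()
    for a, b in itertools.combinations(progeny_means.index, 2):
        if p_progeny < alpha and mse > 0:
            se = np.sqrt(mse * (1.0 / sizes[a] + 1.0 / sizes[b]))
            t = (progeny_means[a] - progeny_means[b]) / se
            p = 2.0 * stats.t.sf(abs(t), df_resid)
        else:
            # unprotected: ANOVA not significant -> no pairwise claims
            t, p = np.nan, np.nan
        rows.append({"progeny_a": a, "progeny_b": b, "t": t, "p": p})
        if not (p < alpha):  # NaN counts as not-different
            not_different.add(frozenset((a, b)))
    letters = _letter_groups(progeny_means, not_different)
    return CiAnovaResult(
        anova=anova,
        shapiro_p=shapiro_p,
        bartlett_p=bartlett_p,
        letters=letters,
        progeny_means=progeny_means,
        pairwise_lsd=pd.DataFrame(rows),
    )
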