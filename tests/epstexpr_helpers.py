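"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's own code paths: sums of squares are
accumulated from group means by hand, so they can arbitrate the vectorized
implementations.
"""

import numpy as np


def anova_ss_oracle(y, is_female, is_dan):
    """F statistics for the additive two-way layout by explicit SS decomposition.

    Valid for balanced designs (where type-I and type-II sums of squares
    coincide): SS_factor = sum over levels of n_level*(mean_level - grand)^2,
    SS_resid from the additive fitted values grand + sex_dev + progeny_dev.
    """
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    ss_sex = sum(
        (y[mask].size) * (y[mask].mean() - grand) ** 2
        for mask in (is_female, ~is_female)
    )
    ss_prog = sum(
        (y[mask].size) * (y[mask].mean() - grand) ** 2
        for mask in (is_dan, ~is_dan)
    )
    fitted = np.full_like(y, grand)
    for mask in (is_female, ~is_female):
        fitted[mask] += y[mask].mean() - grand
    for mask in (is_dan, ~is_dan):
        fitted[mask] += y[mask].mean() - grand
    ss_resid = ((y - fitted) ** 2).sum()
    df_resid = y.size - 3  # intercept + sex + progeny
    f_sex = (ss_sex / 1) / (ss_resid / df_resid)
    f_prog = (ss_prog / 1) / (ss_resid / df_resid)
    return f_sex, f_prog


def variance_components_oracle(groups):
    """One-way method-of-moments components from explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([g.size for g in groups])
    n, k = sizes.sum(), len(groups)
    grand = np.concatenate(groups).mean()
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(m * (g.mean() - grand) ** 2 for m, g in zip(sizes, groups))
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    return max(0.0, (msb - msw) / n0), msw
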