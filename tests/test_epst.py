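"""Mid-parent additivity test, variance components, eP_ST and the permutation scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epstexpr_helpers import variance_components_oracle
from epstscan.epst import (
    VarianceComponents,
    additive_share,
    additivity_table,
    common_candidates,
    epst,
    midparent_additivity_test,
    permutation_scan,
    variance_components,
)


def _sex_meta(n_per_pop, sex="M"):
    rows = []
    for progeny in ("FRA", "DAN", "HYB"):
        for i in range(n_per_pop):
            rows.append({"sample_id": f"{progeny}{i}", "progeny": progeny, "sex": sex})
    return pd.DataFrame(rows).set_index("sample_id")


class TestAdditivityTest:
    def test_hybrid_at_midparent_is_additive(self, rng):
        fra = 1.0 + 0.3 * rng.normal(size=20)
        dan = 3.0 + 0.3 * rng.normal(size=20)
        hyb = 2.0 + 0.3 * rng.normal(size=20)
        rec = midparent_additivity_test(fra, dan, hyb)
        assert rec.additive
        assert abs(rec.t_statistic) < 4

    def test_ten_se_displacement_rejected(self, rng):
        # power at a 10-pooled-SE shift is essentially 1 at alpha=0.01
        n, sd = 15, 0.5
        se = sd * np.sqrt(1 / n + 1 / (4 * n) + 1 / (4 * n))
        fra = 0.0 + sd * rng.normal(size=n)
        dan = 2.0 + sd * rng.normal(size=n)
        hyb = 1.0 + 10 * se + sd * rng.normal(size=n)
        rec = midparent_additivity_test(fra, dan, hyb)
        assert not rec.additive and rec.p_value < 0.01

    def test_zero_variance_degenerate_cases(self):
        rec = midparent_additivity_test([1, 1], [3, 3], [2, 2])
        assert rec.additive and rec.t_statistic == 0.0
        rec = midparent_additivity_test([1, 1], [3, 3], [2.5, 2.5])
        assert not rec.additive and rec.p_value == 0.0

    def test_small_group_error(self):
        with pytest.raises(ValueError, match="HYB"):
            midparent_additivity_test([1, 2], [1, 2], [1])

    def test_vectorized_table_matches_scalar(self, rng):
        meta = _sex_meta(6)
        values = rng.normal(size=(5, len(meta)))
        m = pd.DataFrame(values, index=[f"t{i}" for i in range(5)], columns=meta.index)
        tab = additivity_table(m, meta)
        for i, t in enumerate(m.index):
            rec = midparent_additivity_test(
                values[i, :6], values[i, 6:12], values[i, 12:], transcript_id=t
            )
            assert tab.loc[t, "p_value"] == pytest.approx(rec.p_value, rel=1e-12)
            assert tab.loc[t, "additive"] == rec.additive


class TestVarianceComponents:
    def test_zero_within_variance_case(self):
        vc = variance_components([0, 0], [1, 1])
        assert vc.sigma2_GW == 0.0
        assert vc.sigma2_GB == pytest.approx(0.5)

    def test_identical_populations_clip_to_zero(self, rng):
        x = rng.normal(size=12)
        vc = variance_components(x, x)
        assert vc.sigma2_GB == 0.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        fra = rng.normal(size=int(rng.integers(2, 15)))
        dan = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 15)))
        vc = variance_components(fra, dan)
        gb, gw = variance_components_oracle([fra, dan])
        assert vc.sigma2_GB == pytest.approx(gb, abs=1e-10)
        assert vc.sigma2_GW == pytest.approx(gw, abs=1e-10)

    def test_component_recovery(self, rng):
        """Moment estimates recover (0.25, 0.25) within 3 MC SEs at n=30."""
        d = np.sqrt(0.5)  # fixed means +-d/2 give sigma2_GB = d^2/2 = 0.25
        n, t = 30, 2000
        gbs, gws = [], []
        for _ in range(t):
            fra = -d / 2 + rng.normal(0, 0.5, n)
            dan = d / 2 + rng.normal(0, 0.5, n)
            vc = variance_components(fra, dan)
            gbs.append(vc.sigma2_GB)
            gws.append(vc.sigma2_GW)
        for est, truth in ((np.array(gbs), 0.25), (np.array(gws), 0.25)):
            se = est.std() / np.sqrt(t)
            assert abs(est.mean() - truth) < 3 * se

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            variance_components([1.0], [1, 2, 3])


class TestEpst:
    @pytest.mark.parametrize(
        "gb,gw,expected", [(1, 1, 1 / 3), (0, 5, 0.0), (0.5, 0, 1.0), (0, 0, 0.0)]
    )
    def test_closed_form_values(self, gb, gw, expected):
        assert epst(VarianceComponents(gb, gw)) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        fra = rng.normal(size=20)
        dan = 0.7 + rng.normal(size=20)
        base = epst(variance_components(fra, dan))
        scaled = epst(variance_components(13.7 * fra, 13.7 * dan))
        assert scaled == pytest.approx(base, rel=1e-12)
        assert 0.0 <= base <= 1.0


class TestPermutationScan:
    def test_deterministic_given_seed(self, rng):
        meta = _sex_meta(8)
        m = pd.DataFrame(rng.normal(size=(40, len(meta))),
                         index=[f"t{i}" for i in range(40)], columns=meta.index)
        a = permutation_scan(m, meta, sex="M", n_perm=100, seed=5)
        b = permutation_scan(m, meta, sex="M", n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_n_perm_zero_error(self, rng):
        meta = _sex_meta(4)
        m = pd.DataFrame(rng.normal(size=(5, len(meta))),
                         index=[f"t{i}" for i in range(5)], columns=meta.index)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_scan(m, meta, sex="M", n_perm=0)

    def test_planted_differentiation_detected(self, rng):
        """Transcripts with true P_ST = 0.5 flagged against a null background."""
        n = 30
        meta = _sex_meta(n)
        n_null, n_hot = 500, 10
        values = rng.normal(0, 0.5, size=(n_null + n_hot, len(meta)))
        # P_ST = 0.5 <=> sigma2_GB = 2 sigma2_GW = 0.5 -> |m1-m2| = 1
        fra_cols = meta["progeny"] == "FRA"
        dan_cols = meta["progeny"] == "DAN"
        values[:n_hot, fra_cols.to_numpy()] -= 0.5
        values[:n_hot, dan_cols.to_numpy()] += 0.5
        m = pd.DataFrame(values, index=[f"t{i}" for i in range(n_null + n_hot)],
                         columns=meta.index)
        scan = permutation_scan(m, meta, sex="M", n_perm=400, seed=9)
        hot = [f"t{i}" for i in range(n_hot) if f"t{i}" in scan.index]
        flagged = scan.loc[hot, "outlier"].sum()
        assert flagged >= 8

    def test_null_distributions_agree_across_seeds(self, rng):
        """The pooled permutation null is stable under the seed (KS p > 0.01)."""
        meta = _sex_meta(10)
        m = pd.DataFrame(rng.normal(size=(60, len(meta))),
                         index=[f"t{i}" for i in range(60)], columns=meta.index)
        nulls = []
        for seed in (1, 2):
            scan, null = permutation_scan(m, meta, sex="M", n_perm=60, seed=seed,
                                          return_null=True)
            nulls.append(rng.choice(null, size=500, replace=False))
        assert stats.ks_2samp(nulls[0], nulls[1]).pvalue > 0.01

    def test_estimator_bias_shrinks_with_n(self):
        """Mean null eP_ST is small, positive, and decreasing in sample size."""
        means = []
        for n in (10, 30, 100):
            rng = np.random.default_rng(77)
            meta = _sex_meta(n)
            m = pd.DataFrame(rng.normal(size=(300, len(meta))),
                             index=[f"t{i}" for i in range(300)], columns=meta.index)
            scan = permutation_scan(m, meta, sex="M", n_perm=1, seed=0)
            means.append(scan["epst"].mean())
        assert means[0] > means[1] > means[2] > 0


class TestCommonCandidates:
    def test_intersection_ordered_by_first(self):
        assert common_candidates(["a", "b", "c"], ["c", "b", "d"]) == ["b", "c"]

    def test_empty_list_gives_empty(self):
        assert common_candidates(["a"], []) == []

    def test_identical_lists(self):
        assert common_candidates(["x", "y"], ["x", "y"]) == ["x", "y"]


def test_additive_share_matches_reported_rounding():
    assert round(additive_share([953, 980], 31918)) == 6
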