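"""RDA, variance partitioning, contribution tails and Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from epstscan.ordination import (
    cluster_transcripts,
    contribution_tails,
    design_matrix,
    rda_fit,
    variance_partition,
)


def _frame(values, row_prefix, col_prefix):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{row_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{col_prefix}{j}" for j in range(values.shape[1])],
    )


def _brute_force_rda(y, x):
    """Oracle: explicit normal-equation fit then PCA of the fitted values."""
    y = y - y.mean(axis=0)
    x = x - x.mean(axis=0)
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    fitted = x @ beta
    cov = fitted.T @ fitted / (y.shape[0] - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    return eig[eig > 1e-12]


class TestDesignMatrix:
    def test_single_factor_reference_coding(self):
        meta = pd.DataFrame({"sex": ["M", "F", "M"]}, index=["a", "b", "c"])
        dm = design_matrix(meta, ["sex"])
        assert list(dm.columns) == ["sex:M"]
        np.testing.assert_array_equal(dm.to_numpy().ravel(), [1, 0, 1])

    def test_two_factor_column_count(self, balanced_metadata):
        meta = balanced_metadata.copy()
        meta.loc[meta.index[:4], "progeny"] = "HYB"  # third level
        dm = design_matrix(meta, ["sex", "progeny"])
        assert dm.shape[1] == 1 + 2

    def test_empty_factor_list(self, balanced_metadata):
        assert design_matrix(balanced_metadata, []).shape == (16, 0)

    def test_single_level_factor_error(self):
        meta = pd.DataFrame({"sex": ["M", "M"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="single level"):
            design_matrix(meta, ["sex"])


class TestRdaFit:
    def test_single_transcript_reduces_to_r_squared(self, rng):
        x = rng.normal(size=(20, 1))
        y = 2 * x + rng.normal(size=(20, 1))
        res = rda_fit(_frame(y, "s", "t"), _frame(x, "s", "x"))
        r = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert res.constrained_fraction == pytest.approx(r**2, rel=1e-10)

    def test_orthogonal_predictor_explains_nothing(self, rng):
        y = rng.normal(size=(12, 5))
        y = y - y.mean(axis=0)
        x = rng.normal(size=(12, 1))
        x = x - x.mean(axis=0)
        # project x out of every response column
        y = y - x @ (x.T @ y) / (x.T @ x)
        res = rda_fit(_frame(y, "s", "t"), _frame(x, "s", "x"))
        assert res.constrained_fraction <= 1e-10

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(8, 20))
        t = int(rng.integers(3, 12))
        y = rng.normal(size=(n, t))
        levels = rng.integers(0, 2, size=(n, 2)).astype(float)
        res = rda_fit(_frame(y, "s", "t"), _frame(levels, "s", "x"))
        oracle = _brute_force_rda(y, levels)
        np.testing.assert_allclose(res.axis_eigenvalues, oracle, rtol=1e-8)

    def test_partial_with_empty_z_equals_full(self, rng):
        y = _frame(rng.normal(size=(15, 6)), "s", "t")
        x = _frame(rng.integers(0, 2, size=(15, 2)).astype(float), "s", "x")
        z = pd.DataFrame(index=y.index)
        full = rda_fit(y, x)
        partial = rda_fit(y, x, Z=z)
        np.testing.assert_array_equal(full.axis_eigenvalues, partial.axis_eigenvalues)

    def test_eigenvalue_sum_bounded_by_total(self, rng):
        y = _frame(rng.normal(size=(14, 7)), "s", "t")
        x = _frame(rng.integers(0, 2, size=(14, 2)).astype(float), "s", "x")
        res = rda_fit(y, x)
        assert res.axis_eigenvalues.sum() <= res.total_variance * (1 + 1e-8)

    def test_rank_deficient_design_error(self, rng):
        y = _frame(rng.normal(size=(10, 3)), "s", "t")
        col = rng.integers(0, 2, size=10).astype(float)
        x = _frame(np.column_stack([col, col]), "s", "x")
        with pytest.raises(ValueError, match="rank"):
            rda_fit(y, x)


class TestVariancePartition:
    @staticmethod
    def _meta(n_per_cell, progenies=("DAN", "FRA", "HYB")):
        rows = []
        for progeny in progenies:
            for sex in ("F", "M"):
                for i in range(n_per_cell):
                    rows.append({"sample_id": f"{progeny}{sex}{i}",
                                 "progeny": progeny, "sex": sex})
        return pd.DataFrame(rows).set_index("sample_id")

    def test_sex_only_signal_gives_null_progeny_share(self, rng):
        meta = self._meta(30)
        n = len(meta)
        sex_col = (meta["sex"] == "F").to_numpy(float)
        y = 1.5 * sex_col[:, None] * rng.normal(size=(1, 50)) + 0.5 * rng.normal(size=(n, 50))
        part = variance_partition(_frame(y, "", "t").set_axis(meta.index), meta)
        assert part.progeny_fraction_of_explained < 0.02

    def test_balanced_orthogonal_design_shares_sum_to_one(self, rng):
        meta = self._meta(4, progenies=("DAN", "FRA"))
        n = len(meta)
        y = _frame(rng.normal(size=(n, 12)), "", "t").set_axis(meta.index)
        part = variance_partition(y, meta)
        total = part.sex_fraction_of_explained + part.progeny_fraction_of_explained
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_effects_give_equal_shares(self):
        meta = self._meta(4, progenies=("DAN", "FRA"))
        sex = (meta["sex"] == "F").to_numpy(float)
        prog = (meta["progeny"] == "DAN").to_numpy(float)
        # disjoint transcript sets, equal magnitude, zero noise
        y = np.zeros((len(meta), 4))
        y[:, :2] = sex[:, None]
        y[:, 2:] = prog[:, None]
        part = variance_partition(_frame(y, "", "t").set_axis(meta.index), meta)
        assert part.sex_fraction_of_explained == pytest.approx(0.5, abs=1e-10)
        assert part.progeny_fraction_of_explained == pytest.approx(0.5, abs=1e-10)

    def test_full_model_dominates_partials(self, small_dataset):
        from epstscan import preprocess
        m = small_dataset.expression.iloc[:80]
        m = preprocess.impute_missing(preprocess.quantile_normalize(m))
        part = variance_partition(m.T, small_dataset.metadata)
        full_con = part.full.axis_eigenvalues.sum()
        assert part.sex_partial.axis_eigenvalues.sum() <= full_con * (1 + 1e-8)
        assert part.progeny_partial.axis_eigenvalues.sum() <= full_con * (1 + 1e-8)


class TestContributionTails:
    def test_thousand_scores_give_two(self, rng):
        scores = pd.Series(rng.normal(size=1000),
                           index=[f"t{i}" for i in range(1000)])
        tails = contribution_tails(scores)
        assert len(tails) == 2
        assert scores[tails[0]] == scores.min() and scores[tails[-1]] == scores.max()

    def test_symmetric_scores_give_symmetric_set(self):
        vals = np.arange(1, 501, dtype=float)
        scores = pd.Series(np.concatenate([vals, -vals]),
                           index=[f"t{i}" for i in range(1000)])
        tails = contribution_tails(scores)
        assert sorted(scores[tails]) == sorted(-scores[tails])

    def test_identical_scores_error(self):
        with pytest.raises(ValueError, match="identical"):
            contribution_tails(pd.Series([1.0] * 10))


class TestClusterTranscripts:
    def test_planted_blocks_recovered(self, rng):
        base = rng.normal(size=30)
        block1 = base + 0.01 * rng.normal(size=(6, 30))
        block2 = -base + 0.01 * rng.normal(size=(5, 30))
        m = _frame(np.vstack([block1, block2]), "t", "s")
        labels = cluster_transcripts(m, n_clusters=2)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_cluster(self, rng):
        m = _frame(rng.normal(size=(5, 10)), "t", "s")
        assert set(cluster_transcripts(m, n_clusters=1)) == {1}

    def test_duplicate_joins_its_twin(self, rng):
        base = rng.normal(size=(6, 20))
        m = _frame(np.vstack([base, base[0]]), "t", "s")
        labels = cluster_transcripts(m, n_clusters=2)
        assert labels.iloc[6] == labels.iloc[0]

    def test_constant_row_error(self, rng):
        values = rng.normal(size=(4, 8))
        values[2] = 3.0
        with pytest.raises(ValueError, match="constant"):
            cluster_transcripts(_frame(values, "t", "s"))
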