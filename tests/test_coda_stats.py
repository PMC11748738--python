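"""CLR transform, compositional correlations, permutation FDR, PCA, cancor."""

import numpy as np
import pandas as pd
import pytest

from strepclades import (
    cancor_pairs,
    clr_pca,
    clr_pearson,
    clr_transform,
    fdr_cutoff,
    proportionality_rho,
)


class TestClrTransform:
    def test_constant_positive_row_maps_to_zeros(self):
        y = clr_transform(pd.DataFrame([[5.0, 5.0, 5.0]]), pseudocount=0)
        assert np.allclose(y.to_numpy(), 0.0)

    def test_per_sample_scale_invariance(self, rng):
        x = rng.integers(1, 100, size=(1, 6)).astype(float)
        a = clr_transform(pd.DataFrame(x), pseudocount=0)
        b = clr_transform(pd.DataFrame(2 * x), pseudocount=0)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_closed_form_geometric_mean(self):
        y = clr_transform(pd.DataFrame([[2.0, 4.0, 8.0]]), pseudocount=0)
        assert np.allclose(y.to_numpy()[0], [np.log(0.5), 0.0, np.log(2.0)])

    def test_rows_sum_to_zero(self, rng):
        x = rng.integers(0, 50, size=(8, 5))
        y = clr_transform(pd.DataFrame(x), pseudocount=1)
        assert np.allclose(y.sum(axis=1), 0.0, atol=1e-10)

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame(index=[0]))  # no features
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[0.0, 1.0]]), pseudocount=0)
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[-1.0, 1.0]]))


class TestClrPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(5, dtype=float)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = clr_pearson(df, ("a", "b"))
        assert res.rho == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        res = clr_pearson(df, ("a", "b"))
        xa, xb = df["a"].to_numpy(), df["b"].to_numpy()
        oracle = (
            np.sum((xa - xa.mean()) * (xb - xb.mean()))
            / np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((xb - xb.mean()) ** 2))
        )
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_column_gives_nan(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        res = clr_pearson(df, ("a", "b"))
        assert np.isnan(res.rho)

    def test_all_pairs_mode_applies_bh(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        out = clr_pearson(df)
        assert len(out) == 6
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_scale_invariance_through_clr(self, rng):
        counts = pd.DataFrame(rng.integers(1, 200, size=(12, 5)).astype(float))
        scaled = counts.mul(rng.uniform(0.5, 5.0, size=12), axis=0)
        a = clr_pearson(clr_transform(counts, pseudocount=0), (0, 1))
        b = clr_pearson(clr_transform(scaled, pseudocount=0), (0, 1))
        assert a.rho == pytest.approx(b.rho, abs=1e-12)


class TestProportionality:
    def test_identical_columns_give_one(self):
        x = np.arange(6, dtype=float)
        df = pd.DataFrame({"a": x, "b": x})
        assert proportionality_rho(df).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_column_gives_minus_one(self):
        x = np.arange(6, dtype=float) - 2.5
        df = pd.DataFrame({"a": x, "b": -x})
        assert proportionality_rho(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_dual_formulas_agree(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        rho = proportionality_rho(df)
        for i in "abcd":
            for j in "abcd":
                # oracle: 1 - var(y_i - y_j) / (var(y_i) + var(y_j))
                oracle = 1.0 - (df[i] - df[j]).var() / (df[i].var() + df[j].var())
                assert rho.loc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_diagonal_exactly_one_and_symmetric(self, rng):
        df = pd.DataFrame(rng.normal(size=(7, 5)))
        rho = proportionality_rho(df).to_numpy()
        assert (np.diag(rho) == 1.0).all()
        assert np.allclose(rho, rho.T, atol=1e-14)


class TestFdrCutoff:
    def test_null_data_reports_unattainable(self):
        """Data that is itself a permutation null should attain no cutoff in
        the vast majority of seeded runs."""
        unattained = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame(rng.normal(size=(12, 6)))
            cutoff, _ = fdr_cutoff(df, alpha=0.05, n_perm=30, seed=seed)
            if cutoff is None:
                unattained += 1
        assert unattained >= 0.95 * runs

    def test_planted_proportional_pair_is_retained(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        df["p1"] = x
        df["p2"] = x  # perfectly proportional pair
        cutoff, table = fdr_cutoff(df, alpha=0.05, n_perm=50, seed=7)
        assert cutoff is not None
        rho = proportionality_rho(df)
        assert abs(rho.loc["p1", "p2"]) >= cutoff

    def test_vacuous_alpha_returns_smallest_grid_cutoff(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        cutoff, _ = fdr_cutoff(df, alpha=1.0, n_perm=5, seed=0)
        assert cutoff == pytest.approx(0.05)

    def test_zero_permutations_is_error(self, rng):
        with pytest.raises(ValueError):
            fdr_cutoff(pd.DataFrame(rng.normal(size=(5, 3))), n_perm=0)


class TestClrPca:
    def test_low_abundance_feature_removed(self):
        counts = pd.DataFrame(
            {
                "big1": [5_000_000, 5_100_000, 4_900_000],
                "big2": [4_000_000, 4_100_000, 3_900_000],
                "tiny": [45, 55, 50],  # ~0.0005% mean abundance
            }
        )
        res = clr_pca(counts, min_abundance_pct=0.001)
        assert "tiny" not in res.loadings.index
        assert {"big1", "big2"} <= set(res.loadings.index)

    def test_duplicate_samples_get_identical_scores(self):
        counts = pd.DataFrame(
            [[10, 20, 30], [40, 5, 60], [10, 20, 30]], columns=list("abc"),
            dtype=float,
        )
        res = clr_pca(counts, min_abundance_pct=0.0)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[2], atol=1e-10)

    def test_component_variances_match_eigendecomposition(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(10, 6)).astype(float))
        res = clr_pca(counts, min_abundance_pct=0.0, pseudocount=1)
        y = clr_transform(counts, pseudocount=1).to_numpy()
        y = y - y.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(y, rowvar=False)))[::-1]
        score_var = res.scores.to_numpy().var(axis=0, ddof=1)
        assert np.allclose(score_var[: len(eig)], eig[: len(score_var)], atol=1e-8)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and evr.min() >= 0 and evr.max() <= 1

    def test_too_few_features_after_filter_is_error(self):
        counts = pd.DataFrame({"a": [100.0, 100.0], "b": [0.0001, 0.0001]})
        with pytest.raises(ValueError, match="fewer than 2"):
            clr_pca(counts, min_abundance_pct=1.0)


class TestCancorPairs:
    def test_variable_identical_to_block_column(self, rng):
        block = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
        meta = pd.DataFrame({"v": block["x"]})
        res = cancor_pairs(meta, block, n_perm=19, seed=0)
        assert res["canonical_correlation"].iloc[0] == pytest.approx(1.0)

    def test_single_variable_equals_sqrt_r2(self, rng):
        block = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("xyz"))
        v = rng.normal(size=40)
        res = cancor_pairs(pd.DataFrame({"v": v}, index=block.index), block,
                           n_perm=19, seed=0)
        # oracle: sqrt of R^2 of v regressed on the block (with intercept)
        x = np.column_stack([np.ones(40), block.to_numpy()])
        beta, *_ = np.linalg.lstsq(x, v, rcond=None)
        fitted = x @ beta
        r2 = 1 - np.sum((v - fitted) ** 2) / np.sum((v - v.mean()) ** 2)
        assert res["canonical_correlation"].iloc[0] == pytest.approx(
            np.sqrt(r2), abs=1e-10
        )

    def test_categorical_variable_expands_to_indicators(self, rng):
        block = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        cat = pd.Series(["a", "b", "c"] * 10, index=block.index)
        res = cancor_pairs(pd.DataFrame({"site": cat}), block, n_perm=19, seed=0)
        assert 0.0 <= res["canonical_correlation"].iloc[0] <= 1.0

    def test_independent_variable_rarely_flagged(self):
        """Type-I control of the cc >= 0.4 AND p <= 0.01 double rule."""
        flags = 0
        reps = 500
        rng = np.random.default_rng(42)
        for _ in range(reps):
            block = pd.DataFrame(rng.normal(size=(100, 3)))
            v = pd.DataFrame({"v": rng.normal(size=100)}, index=block.index)
            res = cancor_pairs(v, block, n_perm=199,
                               seed=int(rng.integers(2**31)))
            flags += int(res["significant"].iloc[0])
        assert flags / reps <= 0.02

    def test_constant_variable_is_na_flagged(self, rng):
        block = pd.DataFrame(rng.normal(size=(10, 2)))
        meta = pd.DataFrame({"v": np.ones(10)}, index=block.index)
        res = cancor_pairs(meta, block, n_perm=9, seed=0)
        assert np.isnan(res["canonical_correlation"].iloc[0])
        assert not res["significant"].iloc[0]

    def test_too_few_complete_cases_is_error(self, rng):
        block = pd.DataFrame(rng.normal(size=(4, 2)))
        meta = pd.DataFrame({"v": rng.normal(size=4)}, index=block.index)
        with pytest.raises(ValueError, match="complete cases"):
            cancor_pairs(meta, block, n_perm=9, seed=0)
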