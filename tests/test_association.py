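"""Yeo-Johnson normalization, Spearman correlations, and outlier flags."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import pytest

import phytodiv as pv
from phytodiv.phylo_metrics import lowess_fit


class TestYeoJohnson:
    def test_recovers_identity_lambda_on_normal_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        _, params = pv.yeo_johnson(x)
        assert abs(params.lmbda - 1.0) < 0.2

    def test_output_standardized(self):
        rng = np.random.default_rng(1)
        t, params = pv.yeo_johnson(rng.exponential(size=200))
        assert abs(t.mean()) < 1e-9 and abs(t.std() - 1.0) < 1e-9
        assert params.sd > 0

    def test_order_preserving(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=50) * rng.exponential() + rng.normal()
            t, _ = pv.yeo_johnson(x)
            assert np.array_equal(np.argsort(x), np.argsort(t))

    def test_fixed_lambda_zero_is_log1p(self):
        x = np.array([0.0, 1.0, 3.0, 7.0, 20.0])
        t, params = pv.yeo_johnson(x, lmbda=0.0)
        expected = np.log1p(x)
        expected = (expected - expected.mean()) / expected.std()
        assert np.allclose(t, expected, atol=1e-12)
        assert params.lmbda == 0.0

    def test_nulls_excluded_and_reinserted(self):
        x = np.array([1.0, np.nan, 2.0, 5.0, np.nan, 9.0])
        t, _ = pv.yeo_johnson(x)
        assert np.isnan(t[1]) and np.isnan(t[4])
        assert np.isfinite(t[[0, 2, 3, 5]]).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pv.yeo_johnson([2.0, 2.0, 2.0, 2.0])

    def test_agrees_with_sklearn_power_transformer(self):
        sklearn = pytest.importorskip("sklearn.preprocessing")
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=300)
        t, _ = pv.yeo_johnson(x)
        ref = sklearn.PowerTransformer(method="yeo-johnson", standardize=True)
        t_ref = ref.fit_transform(x[:, None])[:, 0]
        assert np.allclose(t, t_ref, atol=1e-3)


class TestSpearman:
    def test_perfect_antitone(self):
        res = pv.spearman([1, 2, 3], [9, 4, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_identity_has_smallest_attainable_p(self):
        res = pv.spearman([1, 2, 3], [1, 2, 3])
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 3)  # 2 of 3! permutations reach |rho|=1

    def test_exact_p_for_n3_monotone_pair(self):
        res = pv.spearman([10, 20, 30], [1.1, 5.0, 7.2])
        assert res.p == pytest.approx(1 / 3)

    def test_incomplete_pairs_dropped(self):
        res = pv.spearman([1, 2, 3, 4, np.nan], [2, 4, 6, np.nan, 10])
        assert res.n == 3

    def test_too_few_pairs_null(self, caplog):
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            assert pv.spearman([1, 2], [2, 1]) is None

    def test_large_n_uses_t_approximation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = pv.spearman(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_p_consistent_with_permutation_distribution(self):
        # at n=4 the exact two-sided p of a perfect monotone pair is
        # 2/4! = 1/12 (only the two extreme orderings reach |rho| = 1)
        res = pv.spearman([1, 2, 3, 4], [2, 3, 5, 9])
        assert res.p == pytest.approx(1 / 12)

    def test_invariant_under_yeo_johnson(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.lognormal(size=30)
            y = x * 2 + rng.normal(size=30)
            raw = pv.spearman(x, y)
            tx, _ = pv.yeo_johnson(x)
            ty, _ = pv.yeo_johnson(y)
            trans = pv.spearman(tx, ty)
            assert trans.rho == pytest.approx(raw.rho, abs=1e-12)
            assert trans.p == pytest.approx(raw.p, abs=1e-12)


class TestCorrelationMatrix:
    def _profiles(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        fad = rng.lognormal(2, 1, size=n)
        return pd.DataFrame(
            {
                "region": [f"R{i}" for i in range(n)],
                "FAD": fad,
                "MFAD": fad / rng.integers(5, 20, size=n),
                "J": rng.beta(5, 2, size=n),
                "PD": fad * 0.5 + rng.normal(0, 1, size=n),
            }
        )

    def test_unit_diagonal_and_symmetry(self):
        from phytodiv.association import pivot_rho

        tidy = pv.correlation_matrix(self._profiles(), variables=["FAD", "MFAD", "J", "PD"])
        mat = pivot_rho(tidy)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)

    def test_pairwise_deletion_reports_per_pair_n(self):
        prof = self._profiles()
        prof.loc[:4, "J"] = np.nan
        tidy = pv.correlation_matrix(prof, variables=["FAD", "J", "PD"])
        n_fad_pd = tidy.query("var_a == 'FAD' and var_b == 'PD'")["n"].iloc[0]
        n_fad_j = tidy.query("var_a == 'FAD' and var_b == 'J'")["n"].iloc[0]
        assert n_fad_pd == len(prof) and n_fad_j == len(prof) - 5

    def test_independent_evenness_uncorrelated_with_richness(self):
        # evenness constructed independently of richness: |rho(J, FAD)| small
        rng = np.random.default_rng(6)
        n = 300
        prof = pd.DataFrame(
            {
                "region": [f"R{i}" for i in range(n)],
                "FAD": rng.lognormal(3, 1, size=n),
                "J": rng.beta(8, 3, size=n),
            }
        )
        tidy = pv.correlation_matrix(prof, variables=["FAD", "J"])
        rho = tidy.query("var_a == 'FAD' and var_b == 'J'")["rho"].iloc[0]
        assert abs(rho) < 0.1

    def test_all_null_variable_dropped_with_warning(self, caplog):
        prof = self._profiles()
        prof["J"] = np.nan
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            tidy = pv.correlation_matrix(prof, variables=["FAD", "J", "PD"])
        assert "J" not in set(tidy["var_a"]) | set(tidy["var_b"])
        assert "all-null" in caplog.text

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="10"):
            pv.correlation_matrix(self._profiles(n=5), variables=["FAD", "PD"])


class TestFlagOutliers:
    def _frame(self, n=60, seed=7):
        # bounded noise keeps all baseline residuals within 2 SD, so only
        # a planted displacement can trip the flag
        rng = np.random.default_rng(seed)
        pd_vals = np.sort(rng.uniform(0, 10, size=n))
        j = 0.5 + 0.03 * pd_vals + rng.uniform(-0.03, 0.03, size=n)
        return pd.DataFrame(
            {"region": [f"R{i:02d}" for i in range(n)], "PD": pd_vals, "J": j}
        )

    def test_planted_outlier_recovered(self):
        prof = self._frame()
        resid = prof["J"] - lowess_fit(prof["PD"], prof["J"])
        prof.loc[30, "J"] += 5 * resid.std(ddof=1)
        flags = pv.flag_outliers(prof, x_var="PD", y_var="J", k=2)
        high = [f for f in flags if f.direction == "high"]
        assert [f.region for f in high] == ["R30"]

    def test_points_on_curve_no_flags(self):
        prof = self._frame()
        prof["J"] = 0.5 + 0.03 * prof["PD"]  # exactly linear, zero residuals
        assert pv.flag_outliers(prof, x_var="PD", y_var="J", k=2) == []

    def test_infinite_threshold_no_flags(self):
        assert pv.flag_outliers(self._frame(), k=math.inf) == []

    def test_invariant_to_row_order(self):
        prof = self._frame()
        prof.loc[10, "J"] += 0.3
        shuffled = prof.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert pv.flag_outliers(prof, k=2) == pv.flag_outliers(shuffled, k=2)

    def test_low_outlier_direction(self):
        prof = self._frame()
        resid = prof["J"] - lowess_fit(prof["PD"], prof["J"])
        prof.loc[20, "J"] -= 5 * resid.std(ddof=1)
        flags = pv.flag_outliers(prof, k=2)
        assert any(f.region == "R20" and f.direction == "low" for f in flags)
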