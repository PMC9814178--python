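import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgsquant.errors import DataError
from mgsquant.stats import (
    adjust_richness, bh_adjust, chi_squared_table, cliffs_delta, contrast_table,
    rank_contrast, spearman_panel,
)

floats_list = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=30
)


class TestRankContrast:
    def test_exact_small_sample_p(self):
        # all 20 rank arrangements enumerated: most extreme * 2 -> 0.1
        res = rank_contrast([1, 2, 3, 10, 20, 30], ["x", "x", "x", "y", "y", "y"])
        assert res.p == pytest.approx(0.1)
        assert res.test == "mann-whitney-exact"

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Enumerate every assignment of the pooled values into two groups
        and count arrangements with a U at least as extreme."""
        x = rng.normal(size=4)
        y = rng.normal(size=3) + 0.5
        res = rank_contrast(np.concatenate([x, y]), ["a"] * 4 + ["b"] * 3)
        pooled = np.concatenate([x, y])

        def u_stat(xs, ys):
            return sum(1 for xi in xs for yi in ys if xi > yi)

        u_obs = u_stat(x, y)
        mu = len(x) * len(y) / 2
        count = total = 0
        for combo in itertools.combinations(range(7), 4):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(7) if i not in combo]]
            if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert res.p == pytest.approx(count / total)

    def test_identical_groups_symmetric(self):
        res = rank_contrast([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.p > 0.9
        assert res.cliffs_delta == 0.0

    def test_ties_fall_back_to_asymptotic(self):
        res = rank_contrast([1, 1, 2, 2, 3, 3], ["a"] * 3 + ["b"] * 3)
        assert res.test == "mann-whitney-asymptotic"

    def test_three_groups_use_kruskal(self):
        res = rank_contrast([1, 2, 5, 6, 9, 10], ["a", "a", "b", "b", "c", "c"])
        assert res.test == "kruskal-wallis"
        assert res.cliffs_delta is None

    def test_small_group_is_error(self):
        with pytest.raises(DataError):
            rank_contrast([1, 2, 3], ["a", "a", "b"])

    def test_kruskal_null_calibration(self, rng):
        """Under identical group distributions the p-values are roughly
        uniform (KS test at a loose level)."""
        from scipy.stats import kstest

        pvals = []
        for _ in range(300):
            vals = rng.normal(size=30)
            groups = np.repeat(["a", "b", "c"], 10)
            pvals.append(rank_contrast(vals, groups).p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCliffsDelta:
    def test_complete_separation(self):
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0

    def test_hand_computed_quarter(self):
        assert cliffs_delta([1, 2], [1, 3]) == pytest.approx(-0.25)

    def test_identical_is_zero(self):
        assert cliffs_delta([1, 2, 2], [1, 2, 2]) == 0.0

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            cliffs_delta([], [1.0])

    @given(floats_list, floats_list)
    @settings(max_examples=80, deadline=None)
    def test_antisymmetry(self, x, y):
        assert cliffs_delta(x, y) == pytest.approx(-cliffs_delta(y, x), abs=1e-12)

    @given(floats_list, floats_list)
    @settings(max_examples=80, deadline=None)
    def test_matches_pairwise_oracle(self, x, y):
        gt = sum(1 for a in x for b in y if a > b)
        lt = sum(1 for a in x for b in y if a < b)
        expect = (gt - lt) / (len(x) * len(y))
        assert cliffs_delta(x, y) == pytest.approx(expect, abs=1e-12)


class TestBhAdjust:
    def test_stepup_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_stepup_oracle(self, p):
        """q_i = min over k with p_(k) >= p_i of m p_(k) / k, done with
        explicit loops over the sorted vector."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expect = np.empty(m)
        sorted_p = p[order]
        for pos in range(m):
            candidates = [m * sorted_p[k] / (k + 1) for k in range(pos, m)]
            expect[order[pos]] = min(1.0, min(candidates))
        assert np.allclose(bh_adjust(p), expect, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSpearmanPanel:
    def panel(self, x, y):
        feats = pd.DataFrame([x], index=["f"], columns=[f"s{i}" for i in range(len(x))])
        meta = pd.DataFrame({"v": y}, index=feats.columns)
        return spearman_panel(feats, meta)

    def test_monotone_is_one(self):
        out = self.panel([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        out = self.panel([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        out = self.panel([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert out["rho"].iloc[0] == pytest.approx(0.8)

    def test_constant_vector_recorded_missing(self):
        out = self.panel([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        assert np.isnan(out["rho"].iloc[0])

    def test_display_tiers(self, rng):
        feats = pd.DataFrame(rng.normal(size=(3, 40)),
                             index=list("abc"), columns=[f"s{i}" for i in range(40)])
        meta = pd.DataFrame({"v1": feats.loc["a"] + rng.normal(scale=0.1, size=40),
                             "v2": rng.normal(size=40)}, index=feats.columns)
        out = spearman_panel(feats, meta)
        strong = out[(out["feature"] == "a") & (out["variable"] == "v1")]
        assert bool(strong["strong"].iloc[0])


class TestChiSquared:
    def test_cohort_smoking_2x3(self):
        # counts printed for never/previous/current smoking, cases vs controls
        stat, df, p = chi_squared_table([[50, 56, 40], [90, 41, 15]], continuity=False)
        assert df == 2
        assert p == pytest.approx(3.5e-06, rel=0.05)

    def test_activity_sex_2x2_with_yates(self):
        stat, df, p = chi_squared_table([[8, 4], [11, 8]], continuity=True)
        assert df == 1
        assert round(p, 2) == 0.91

    def test_activity_smoking_2x3(self):
        stat, df, p = chi_squared_table([[5, 3, 4], [4, 8, 7]], continuity=False)
        assert round(p, 2) == 0.43

    def test_default_continuity_is_2x2_only(self):
        _, _, p_auto = chi_squared_table([[8, 4], [11, 8]])
        _, _, p_yates = chi_squared_table([[8, 4], [11, 8]], continuity=True)
        assert p_auto == p_yates
        _, _, p3_auto = chi_squared_table([[50, 56, 40], [90, 41, 15]])
        _, _, p3_off = chi_squared_table([[50, 56, 40], [90, 41, 15]], continuity=False)
        assert p3_auto == p3_off

    def test_identical_rows_give_p_one(self):
        stat, df, p = chi_squared_table([[98, 50], [98, 50]], continuity=False)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_is_error(self):
        with pytest.raises(DataError):
            chi_squared_table([[0, 5], [0, 7]])


class TestAdjustRichness:
    def test_orthogonal_covariates_leave_richness_unchanged(self):
        richness = pd.Series([10.0, 20.0, 10.0, 20.0], index=list("abcd"))
        covs = pd.DataFrame({"z": [1.0, 1.0, -1.0, -1.0]}, index=list("abcd"))
        out = adjust_richness(richness, covs)
        pd.testing.assert_series_equal(out, richness.rename("adjusted_richness"))

    def test_exact_linear_dependence_becomes_constant(self):
        covs = pd.DataFrame({"bmi": [20.0, 22, 24, 26, 28]}, index=list("abcde"))
        richness = pd.Series(3.0 * covs["bmi"] + 5, index=covs.index)
        out = adjust_richness(richness, covs)
        assert np.allclose(out, richness.mean())

    def test_collinear_design_is_error(self):
        covs = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]}, index=list("wxyz"))
        richness = pd.Series([1.0, 2, 3, 4], index=covs.index)
        with pytest.raises(DataError, match="b"):
            adjust_richness(richness, covs)

    def test_adjustment_recovers_planted_relapse_signal(self, rng):
        """richness = f(covariates) + gamma * relapses + noise, with the
        covariate confounded against relapses: the adjusted correlation must
        recover gamma's sign and beat the unadjusted one on average."""
        from scipy.stats import spearmanr

        gamma = 4.0
        wins = better = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            n = 40
            relapses = r.poisson(1.0, n).astype(float)
            # covariate masks the relapse effect: without adjustment the raw
            # correlation is pushed negative
            bmi = 24 + 2.0 * relapses + r.normal(0, 1, n)
            richness = 100 - 6.0 * bmi + gamma * relapses + r.normal(0, 3, n)
            idx = [f"s{i}" for i in range(n)]
            adj = adjust_richness(pd.Series(richness, index=idx),
                                  pd.DataFrame({"bmi": bmi}, index=idx))
            rho_adj = spearmanr(adj, relapses).statistic
            rho_raw = spearmanr(richness, relapses).statistic
            wins += rho_adj > 0
            better += rho_adj > rho_raw
        assert wins / n_rep >= 0.9
        assert better / n_rep >= 0.9


class TestContrastTable:
    def test_family_wide_bh_and_flags(self, rng):
        n = 30
        feats = pd.DataFrame(rng.normal(size=(10, n)),
                             index=[f"f{i}" for i in range(10)],
                             columns=[f"s{i}" for i in range(n)])
        groups = np.array(["a"] * 15 + ["b"] * 15)
        feats.loc["f0", groups == "a"] += 50.0
        out = contrast_table(feats, groups)
        assert out.index[0] == "f0"
        assert bool(out.loc["f0", "significant"])
        assert np.allclose(out["q"].to_numpy(), bh_adjust(out["p"].to_numpy()))
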