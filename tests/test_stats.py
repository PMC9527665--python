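"""Closed-form statistics checked against hand-derived values and, as an
independent oracle, scipy/statsmodels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aluedit.stats import (
    anova_one_way,
    anova_two_way,
    bh_adjust,
    chi2_gof,
    dunn_posthoc,
    kruskal_wallis,
    welch_t,
)


class TestWelch:
    def test_hand_derived_toy(self):
        # x = {10,12,14}, y = {5,6,7}: s2x=4, s2y=1, se2 = 4/3 + 1/3
        res = welch_t([10, 12, 14], [5, 6, 7])
        se2 = 4 / 3 + 1 / 3
        t_hand = (12 - 6) / math.sqrt(se2)
        df_hand = se2**2 / ((4 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)
        assert df_hand == pytest.approx(50 / 17)

    def test_identical_vectors_give_null_result(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetric_in_groups(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 2, size=5)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)
        assert a.df == pytest.approx(b.df)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            mine = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)
            assert mine.df == pytest.approx(ref.df, abs=1e-8)


class TestChi2:
    def test_no_deviation_gives_unit_p(self):
        res = chi2_gof([500, 500], [500, 500])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            obs = rng.integers(0, 500, size=k).astype(float)
            if obs.sum() == 0:
                obs[0] = 1
            mine = chi2_gof(obs)
            ref = sps.chisquare(obs)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi2_gof([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            chi2_gof([1, 2], [1, 0])


class TestBH:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=200, derandomize=True)
    def test_never_decreases_and_stays_in_unit_interval(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all() and (adj >= 0.0).all()

    def test_permutation_invariant(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestAnova:
    def test_one_way_matches_scipy(self, rng):
        for _ in range(50):
            groups = [
                rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 15))
                for _ in range(int(rng.integers(2, 6)))
            ]
            mine = anova_one_way(groups)
            ref = sps.f_oneway(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_way_hand_computed_2x2(self):
        # cells (A1,B1)={1,3} (A1,B2)={2,4} (A2,B1)={5,7} (A2,B2)={10,12}
        values = [1, 3, 2, 4, 5, 7, 10, 12]
        fa = ["a1"] * 4 + ["a2"] * 4
        fb = ["b1", "b1", "b2", "b2"] * 2
        res = anova_two_way(values, fa, fb)
        # grand=5.5; A means 2.5/8.5 -> SS_A=2*2*(9+9)=72
        # B means 4/7 -> SS_B = 2*2*(2.25+2.25)=18
        # cell means 2,3,6,11; interaction deviations ±1 -> SS_AB=2*4=8
        # within-cell SS = 2 per cell -> SS_E=8, df_e=4, MS_E=2
        assert res["factor_a"].statistic == pytest.approx(72 / 2)
        assert res["factor_b"].statistic == pytest.approx(18 / 2)
        assert res["interaction"].statistic == pytest.approx(8 / 2)
        assert res["factor_a"].extra["df_denom"] == 4

    def test_two_way_no_effect_gives_zero_f(self):
        values = [3.0] * 8
        fa = ["a1"] * 4 + ["a2"] * 4
        fb = ["b1", "b1", "b2", "b2"] * 2
        res = anova_two_way(values, fa, fb)
        assert res["factor_a"].statistic == 0.0
        assert res["factor_b"].statistic == 0.0
        assert res["factor_a"].p == pytest.approx(1.0)

    def test_two_way_matches_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for _ in range(20):
            a_levels, b_levels, n = (
                int(rng.integers(2, 4)), int(rng.integers(2, 4)), int(rng.integers(2, 5))
            )
            rows = []
            for la in range(a_levels):
                for lb in range(b_levels):
                    for _ in range(n):
                        rows.append(
                            {"y": rng.normal(la + 0.5 * lb), "A": f"a{la}", "B": f"b{lb}"}
                        )
            df = pd.DataFrame(rows)
            mine = anova_two_way(df["y"], df["A"], df["B"])
            fit = ols("y ~ C(A) * C(B)", data=df).fit()
            ref = sm.stats.anova_lm(fit, typ=2)
            assert mine["factor_a"].statistic == pytest.approx(ref.loc["C(A)", "F"], abs=1e-8)
            assert mine["factor_b"].statistic == pytest.approx(ref.loc["C(B)", "F"], abs=1e-8)
            assert mine["interaction"].statistic == pytest.approx(
                ref.loc["C(A):C(B)", "F"], abs=1e-8
            )
            assert mine["factor_a"].p == pytest.approx(ref.loc["C(A)", "PR(>F)"], abs=1e-8)

    def test_two_way_unbalanced_rejected(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        fa = ["a1"] * 5 + ["a2"] * 4
        fb = ["b1", "b1", "b2", "b2", "b2", "b1", "b1", "b2", "b2"]
        with pytest.raises(ValueError, match="balanced"):
            anova_two_way(values, fa, fb)


class TestRankTests:
    def test_kruskal_wraps_reference(self, rng):
        groups = [rng.normal(size=10), rng.normal(1, 1, size=12)]
        mine = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_dunn_pairs_and_ranges(self, rng):
        groups = {
            "a": rng.normal(size=12),
            "b": rng.normal(2, 1, size=12),
            "c": rng.normal(size=12),
        }
        out = dunn_posthoc(groups, adjust="none")
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(0 <= p <= 1 for p in out.values())
        # strongly separated pair should be smallest
        assert out[("a", "b")] < out[("a", "c")]
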