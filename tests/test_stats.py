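"""Delta statistics, OLS/ANOVA oracles, and fluorescence indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from leafgas.stats import (
    delta_change,
    delta_table,
    fv_fm,
    one_way_anova,
    ols_regression,
    phi_psii,
    two_way_anova,
)


class TestDeltaChange:
    def test_wheat_gs_means(self):
        """Wheat Gs_H2O 511.2 -> 416.4 mmol m-2 s-1 is 18.5% lower."""
        dc = delta_change(511.2, 416.4)
        assert dc.pct_of_ambient == pytest.approx(81.5, abs=0.05)
        assert dc.pct_lower == pytest.approx(18.5, abs=0.05)

    def test_sunflower_gs_means(self):
        """Sunflower Gs_H2O 976.5 -> 498.6 mmol m-2 s-1 is 48.9% lower."""
        dc = delta_change(976.5, 498.6)
        assert dc.pct_lower == pytest.approx(48.9, abs=0.05)

    def test_equal_values_give_100(self):
        assert delta_change(5.0, 5.0).pct_of_ambient == 100.0

    def test_nonpositive_ambient_rejected(self):
        with pytest.raises(ValueError):
            delta_change(0.0, 5.0)

    @given(ambient=st.floats(0.1, 1e4), elevated=st.floats(0.0, 1e4),
           c=st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=100)
    def test_multiplicative_scale_invariance(self, ambient, elevated, c):
        d1 = delta_change(ambient, elevated).pct_of_ambient
        d2 = delta_change(c * ambient, c * elevated).pct_of_ambient
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestOlsRegression:
    def test_collinear_data(self):
        x = np.arange(10.0)
        res = ols_regression(x, 3.0 * x - 2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(3.0)

    def test_orthogonal_contrast_zero_slope(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = ols_regression(x, y)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        """Against a brute-force normal-equations solve on a 10-point fixture."""
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 10)
        y = 2.5 * x + 1.0 + rng.normal(0, 1, 10)
        res = ols_regression(x, y)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_f_identity(self, seed):
        """F = r2/(1-r2) (n-2) holds to 1e-9 for simple OLS."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n)
        if np.ptp(x) == 0:
            return
        y = rng.normal(size=n) + 0.5 * x
        res = ols_regression(x, y)
        if np.isfinite(res.f_stat):
            want = res.r2 / (1 - res.r2) * (n - 2)
            assert res.f_stat == pytest.approx(want, abs=1e-9)
            assert res.p_value == pytest.approx(
                float(sps.f.sf(want, 1, n - 2)), abs=1e-12)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            ols_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ols_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_three_group_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
        # grand mean 4; between SS = 3[(2-4)^2+(3-4)^2+(7-4)^2] = 42
        # within SS = 3 * 2 = 6; F = (42/2)/(6/6) = 21
        res = one_way_anova(groups)
        assert res.f_stat == pytest.approx(21.0, rel=1e-12)
        assert res.df == (2, 6)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTwoWayAnova:
    @staticmethod
    def _balanced_fixture(seed=3, reps=4):
        rng = np.random.default_rng(seed)
        species = np.repeat([f"sp{i}" for i in range(5)], 2 * reps)
        co2 = np.tile(np.repeat(["ambient", "elevated"], reps), 5)
        effect = {f"sp{i}": i * 1.5 for i in range(5)}
        y = np.array([effect[s] + (0.8 if c == "elevated" else 0.0)
                      + rng.normal(0, 1) for s, c in zip(species, co2)])
        return y, species, co2

    def test_factor_a_f_near_zero_when_only_b_matters(self):
        rng = np.random.default_rng(1)
        a = np.tile(["s1", "s2"], 20)
        b = np.repeat(["amb", "elev"], 20)
        y = np.where(b == "elev", 5.0, 0.0) + rng.normal(0, 1e-9, 40)
        res = two_way_anova(y, a, b)
        assert res["factor_a"].f_stat < 1e-6
        assert res["factor_b"].f_stat > 1e6

    def test_matches_statsmodels_additive_model(self):
        """Independent oracle: statsmodels OLS + anova_lm on the additive
        two-factor model reproduces both F statistics to 1e-10."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        y, species, co2 = self._balanced_fixture()
        res = two_way_anova(y, species, co2)
        df = pd.DataFrame({"y": y, "a": species, "b": co2})
        table = sm.stats.anova_lm(smf.ols("y ~ C(a) + C(b)", df).fit(), typ=2)
        assert res["factor_a"].f_stat == pytest.approx(
            table.loc["C(a)", "F"], abs=1e-10)
        assert res["factor_b"].f_stat == pytest.approx(
            table.loc["C(b)", "F"], abs=1e-10)
        assert res["factor_a"].df == (4, 40 - 5 - 2 + 1)

    def test_ss_decomposition_conserves_total(self):
        y, species, co2 = self._balanced_fixture(seed=9)
        res = two_way_anova(y, species, co2)
        # reconstruct SS from the returned F statistics and dfs
        df_err = res["factor_a"].df[1]
        grand = y.mean()
        ss_total = np.sum((y - grand) ** 2)
        # recompute directly for the balanced design
        mean_a = pd.Series(y).groupby(pd.Series(species)).mean()
        mean_b = pd.Series(y).groupby(pd.Series(co2)).mean()
        ss_a = (len(y) / len(mean_a)) * np.sum((mean_a - grand) ** 2)
        ss_b = (len(y) / len(mean_b)) * np.sum((mean_b - grand) ** 2)
        ss_err = ss_total - ss_a - ss_b
        want_f_a = (ss_a / (len(mean_a) - 1)) / (ss_err / df_err)
        assert res["factor_a"].f_stat == pytest.approx(want_f_a, rel=1e-9)

    def test_unbalanced_rejected(self):
        y = np.arange(7.0)
        a = ["s1"] * 4 + ["s2"] * 3
        b = ["x", "x", "y", "y", "x", "y", "y"]
        with pytest.raises(ValueError):
            two_way_anova(y, a, b)


class TestFluorescenceIndices:
    def test_fv_fm_arithmetic(self):
        assert fv_fm(200.0, 1250.0) == pytest.approx(0.84)

    def test_phi_psii_arithmetic(self):
        assert phi_psii(600.0, 1200.0) == pytest.approx(0.5)

    def test_ordering_contracts(self):
        with pytest.raises(ValueError):
            fv_fm(1250.0, 200.0)
        with pytest.raises(ValueError):
            phi_psii(1200.0, 1200.0)  # fs = fm' boundary rejected


class TestDeltaTable:
    def test_per_species_ratio_of_means(self):
        df = pd.DataFrame({
            "species": ["w"] * 4 + ["s"] * 4,
            "treatment": ["ambient", "ambient", "elevated", "elevated"] * 2,
            "vcmax": [100.0, 110.0, 80.0, 90.0, 50.0, 70.0, 30.0, 30.0],
        })
        out = delta_table(df, ["vcmax"], n_boot=50, seed=0)
        w = out[out.species == "w"].iloc[0]
        assert w.delta_pct == pytest.approx(100 * 85 / 105)
        s = out[out.species == "s"].iloc[0]
        assert s.delta_pct == pytest.approx(50.0)
        assert np.isfinite(s.delta_se)

    def test_missing_treatment_rejected(self):
        df = pd.DataFrame({"species": ["w"], "treatment": ["ambient"],
                           "vcmax": [100.0]})
        with pytest.raises(ValueError):
            delta_table(df, ["vcmax"])
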