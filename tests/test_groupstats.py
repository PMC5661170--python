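"""Clinical statistics: ANCOVA, FDR, partial correlation, power, demographics."""

import numpy as np
import pytest
from scipy import stats

import _oracles as oracle
from wmnet import (PowerSpec, ancova_group_effect, chi_square_2x2, fdr_bh,
                   partial_corr, power_two_sample_t, unpaired_t_from_summary)


class TestAncova:
    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova_group_effect(np.ones(10), np.repeat([0, 1], 5),
                                np.arange(10))

    def test_covariate_only_signal_leaves_group_null(self):
        # values driven purely by age: the age-adjusted group effect is null
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(40):
            age = rng.uniform(20, 60, 30)
            g = np.repeat([0.0, 1.0], 15)
            y = 2.0 * age + rng.normal(0, 0.5, 30)
            ps.append(ancova_group_effect(y, g, age).p)
        assert np.mean(ps) > 0.3

    def test_matches_normal_equations_oracle(self):
        # small fixed dataset solved independently via explicit residualization
        y = np.array([3.1, 4.2, 2.8, 6.5, 7.1, 6.0])
        g = np.array([0, 0, 0, 1, 1, 1], float)
        age = np.array([25, 30, 35, 28, 33, 38], float)
        res = ancova_group_effect(y, g, age)
        X = np.column_stack([np.ones(6), g, age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ beta
        s2 = e @ e / 3
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.statistic == pytest.approx(beta[1] / se, abs=1e-9)
        assert res.df == 3

    def test_constant_age_reduces_to_unpaired_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 20)
        g = np.repeat([0.0, 1.0], 10)
        res = ancova_group_effect(y, g, np.full(20, 33.0))
        t_ref, p_ref = stats.ttest_ind(y[g == 1], y[g == 0])
        assert res.statistic == pytest.approx(t_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            ancova_group_effect(np.arange(4.0), np.array([0, 0, 1, 1.0]),
                                np.arange(4.0))


class TestFdr:
    def test_stepup_hand_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)
        assert np.all(adj <= 0.05)  # all rejected at q = 0.05

    def test_trivial_cases(self):
        assert np.array_equal(fdr_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert fdr_bh([0.037]) == pytest.approx([0.037])
        assert fdr_bh([]).size == 0

    def test_matches_textbook_oracle_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        adj = fdr_bh(p)
        assert np.allclose(adj, oracle.bh_adjust(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPartialCorr:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        cov = rng.normal(0, 1, 20)
        r, _ = partial_corr(x, x + 1e-9 * rng.normal(size=20), cov)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_confound_removal(self):
        # x and y correlated only through the covariate: partial r ~ 0
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(50):
            z = rng.normal(0, 1, 40)
            x = 2 * z + rng.normal(0, 0.3, 40)
            y = -3 * z + rng.normal(0, 0.3, 40)
            rs.append(partial_corr(x, y, z)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        y = 0.4 * x + rng.normal(0, 1, 10)
        z = 0.3 * x - 0.2 * y + rng.normal(0, 1, 10)
        r, _ = partial_corr(x, y, z)
        assert r == pytest.approx(oracle.partial_corr_formula(x, y, z),
                                  abs=1e-9)

    def test_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=25),
                           "y": rng.normal(size=25),
                           "z": rng.normal(size=25)})
        r, p = partial_corr(df["x"], df["y"], df["z"])
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_covariate_equals_plain_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r, _ = partial_corr(x, y, np.full(15, 5.0))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            partial_corr([1, 2, 3], [1, 2, 3], [0, 0, 0])
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="residual"):
            partial_corr(2 * z + 1, np.arange(10.0) ** 2, z)


class TestPower:
    def test_reported_design_reaches_80_percent(self):
        p = power_two_sample_t(PowerSpec())
        assert p >= 0.80

    def test_null_difference_gives_alpha(self):
        p = power_two_sample_t(PowerSpec(diff=0.0))
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_gives_power_one(self):
        assert power_two_sample_t(PowerSpec(diff=100.0)) == pytest.approx(1.0)

    def test_monotone_in_effect_n_and_alpha(self):
        base = power_two_sample_t(PowerSpec())
        assert power_two_sample_t(PowerSpec(diff=0.4)) > base
        assert power_two_sample_t(PowerSpec(n1=40, n2=40)) > base
        assert power_two_sample_t(PowerSpec(alpha=0.10)) > base

    def test_against_monte_carlo_oracle(self):
        # simulate the actual two-sample t-test at the design parameters
        spec = PowerSpec()
        rng = np.random.default_rng(8)
        n_rep = 20000
        a = rng.normal(spec.diff, spec.sd, (n_rep, spec.n1))
        b = rng.normal(0.0, spec.sd, (n_rep, spec.n2))
        t, p = stats.ttest_ind(a, b, axis=1)
        mc = (p < spec.alpha).mean()
        assert power_two_sample_t(spec) == pytest.approx(mc, abs=0.01)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(sd=0.0)
        with pytest.raises(ValueError):
            PowerSpec(n1=1)


class TestDemographics:
    def test_gender_table_chi_square(self):
        # 8F/13M vs 8F/17M: chi2 = 0.1869, p = 0.665
        res = chi_square_2x2([[8, 13], [8, 17]])
        assert res.statistic == pytest.approx(0.1869, abs=5e-5)
        assert res.p == pytest.approx(0.665, abs=5e-4)
        assert res.df == 1

    def test_balanced_table_gives_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 7]])

    def test_education_years_summary_t(self):
        # (14.71, 3.40, 21) vs (16.16, 3.91, 25): |t| ~ 1.33, p ~ 0.19
        res = unpaired_t_from_summary(14.71, 3.40, 21, 16.16, 3.91, 25)
        assert abs(res.statistic) == pytest.approx(1.33, abs=0.01)
        assert res.p == pytest.approx(0.19, abs=0.01)
        assert res.df == 44
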