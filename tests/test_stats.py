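"""Statistics layer: fits, correlations and derived quantities."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from calyxsf.datatypes import CohortParams
from calyxsf.errors import InsufficientDataError, ParameterError
from calyxsf.sfstats import (
    bonferroni,
    conduction_speed,
    logistic_fit,
    pearson_r,
    powerlaw_fit,
    regression_f,
    spearman_rho,
    welch_t_test,
)
from calyxsf.synth import make_cohort, structure_function_records

AMPS = [0.11, 0.26, 0.30, 0.37]
AREAS = [19.2, 23.1, 25.6, 59.7]


class TestPowerLaw:
    def test_exact_log_linear_data(self):
        fit = powerlaw_fit([1.0, 4.0, 9.0], [2.0 * 1, 2.0 * 2, 2.0 * 3])
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)
        assert fit.beta == pytest.approx(2.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self, rng):
        x = rng.uniform(0.5, 50, 3)
        y = rng.uniform(1, 40, 3)
        fit = powerlaw_fit(x, y)
        lx, ly = np.log(x), np.log(y)
        slope = ((lx - lx.mean()) * (ly - ly.mean())).sum() / ((lx - lx.mean()) ** 2).sum()
        intercept = ly.mean() - slope * lx.mean()
        assert fit.alpha == pytest.approx(slope, abs=1e-12)
        assert fit.beta == pytest.approx(math.exp(intercept), rel=1e-12)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(1, 30, 15)
        y = 5.0 * x**0.4 * np.exp(rng.normal(0, 0.2, 15))
        f1 = powerlaw_fit(x, y)
        c = 3.7
        f2 = powerlaw_fit(c * x, y)
        assert f2.alpha == pytest.approx(f1.alpha, abs=1e-9)
        assert f2.beta == pytest.approx(f1.beta * c ** (-f1.alpha), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            powerlaw_fit([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    def test_cohort_recovery_of_generating_parameters(self):
        alphas, betas, rlogs = [], [], []
        for s in range(200):
            areas, rors = structure_function_records(
                make_cohort(CohortParams(n_cells=20, seed=20000 + s))
            )
            fit = powerlaw_fit(areas, rors)
            alphas.append(fit.alpha)
            betas.append(fit.beta)
            rlogs.append(fit.r_log)
        assert abs(np.mean(alphas) - 0.35) <= 0.06
        assert abs(np.mean(betas) - 6.8) <= 0.9
        assert 0.7 <= np.mean(rlogs) <= 0.9


class TestCorrelations:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_prespike_amplitude_vs_area_rounds_to_08(self):
        assert round(pearson_r(AMPS, AREAS), 1) == 0.8

    def test_same_pairs_rho_one(self):
        assert spearman_rho(AMPS, AREAS) == pytest.approx(1.0)

    def test_rho_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


class TestRegression:
    def test_exact_fit_overflow_safe(self):
        res = regression_f([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.F >= 1e12 and res.p == 0.0

    def test_worked_example_f_rounds_to_3(self):
        res = regression_f(np.array(AMPS), np.array(AREAS))
        assert res.df == (1, 2)
        assert round(res.F) == 3

    def test_matches_statsmodels(self, rng):
        x = rng.normal(0, 1, 25)
        z = rng.normal(0, 1, 25)
        y = 2 + 0.5 * x - 0.3 * z + rng.normal(0, 0.4, 25)
        res = regression_f(x, y, covariate=z)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit()
        assert np.allclose(res.params, ref.params, atol=1e-10)
        assert np.allclose(res.bse, ref.bse, atol=1e-10)
        assert res.F == pytest.approx(ref.fvalue, abs=1e-8)
        assert res.p == pytest.approx(ref.f_pvalue, abs=1e-10)

    def test_rank_transform_matches_ranked_ols(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        res = regression_f(x, y, rank_transform=True)
        ref = sm.OLS(sps.rankdata(y), sm.add_constant(sps.rankdata(x))).fit()
        assert np.allclose(res.params, ref.params, atol=1e-10)

    def test_collinear_design_rejected(self):
        with pytest.raises(ParameterError):
            regression_f([1, 2, 3, 4], [1, 2, 3, 4], covariate=[2, 4, 6, 8])


class TestBonferroni:
    def test_paper_context_value(self):
        assert bonferroni(0.0005, m=2) == pytest.approx(0.001)

    def test_clipped_at_one(self):
        assert bonferroni(0.8, m=2) == 1.0

    def test_single_test_identity(self):
        assert bonferroni(0.03, m=1) == pytest.approx(0.03)

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestLogistic:
    def test_symmetric_data_midpoint(self):
        ages = [3.0] * 10 + [5.0] * 10
        present = [0] * 10 + [1] * 10
        fit = logistic_fit(ages, present)
        assert fit.midpoint == pytest.approx(4.0, abs=0.05)

    def test_parameter_recovery_from_printed_values(self):
        ms, ss = [], []
        for s in range(100):
            rng = np.random.default_rng(31000 + s)
            ages = rng.uniform(2, 8, 200)
            p = 1.0 / (1.0 + np.exp(-(ages - 4.1) / 0.7))
            fit = logistic_fit(ages, rng.random(200) < p)
            ms.append(fit.midpoint)
            ss.append(fit.steepness)
        assert abs(np.median(ms) - 4.1) <= 0.2
        assert abs(np.median(ss) - 0.7) <= 0.2

    def test_separated_data_flagged(self):
        ages = [2.0, 2.5, 3.0, 5.0, 5.5, 6.0]
        present = [0, 0, 0, 1, 1, 1]
        fit = logistic_fit(ages, present)
        assert not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            logistic_fit([2, 3, 4], [1, 1, 1])


class TestConductionSpeed:
    def test_printed_p45_value(self):
        assert conduction_speed(2.1) == pytest.approx(0.625)
        assert round(conduction_speed(2.1), 1) == 0.6

    def test_arithmetic(self):
        assert conduction_speed(1.5) == pytest.approx(1.0)

    def test_printed_p23_value(self):
        assert round(conduction_speed(2.5), 1) == 0.5

    def test_latency_below_delay_rejected(self):
        with pytest.raises(ParameterError):
            conduction_speed(0.4)


class TestWelchTTest:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.tvalues[0] == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_computed(self):
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.tvalues[0] == pytest.approx(-3.674, abs=1e-3)
        assert res.df[1] == 4

    def test_matches_reference(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 2, 17)
        res = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.tvalues[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
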