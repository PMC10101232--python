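"""Structural/covariate model: closed forms, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vancoppk as v
from vancoppk.errors import ConfigurationError, DomainError
from vancoppk.model import (
    infusion_concentration,
    initiation_exposure_metrics,
    steady_state_concentration,
)

from conftest import ode_oracle


class TestMaturation:
    def test_half_maturation_at_tma50_is_exactly_half(self):
        assert v.maturation_fraction(26.3, 4.42, 26.3) == pytest.approx(0.5, abs=1e-15)
        assert v.maturation_fraction(33.0, 1.7, 33.0) == pytest.approx(0.5, abs=1e-15)

    def test_saturates_to_one(self):
        assert v.maturation_fraction(1e6, 4.42, 26.3) == pytest.approx(1.0, abs=1e-9)
        assert v.maturation_fraction(np.inf) == 1.0

    def test_numeric_value_matches_log_space_evaluation(self):
        # frozen from direct evaluation of pma^h / (pma^h + tma50^h)
        assert v.maturation_fraction(29.8, 4.42, 26.3) == pytest.approx(0.63465, abs=5e-4)

    @given(st.floats(21.0, 46.0), st.floats(21.0, 46.0))
    def test_strictly_increasing_in_pma(self, a, b):
        lo, hi = sorted((a, b))
        fa, fb = v.maturation_fraction(lo), v.maturation_fraction(hi)
        assert 0.0 < fa < 1.0
        assert fa <= fb
        if hi - lo > 1e-6:
            assert fa < fb

    @pytest.mark.parametrize("pma,hill,tma50", [(-1, 4.42, 26.3), (0, 4.42, 26.3),
                                                (30, 0, 26.3), (30, 4.42, -2)])
    def test_domain_errors(self, pma, hill, tma50):
        with pytest.raises(DomainError):
            v.maturation_fraction(pma, hill, tma50)


class TestTypicalParameters:
    def test_reference_neonate_mature_limit(self, ref_model):
        assert float(ref_model.typical_cl(0.93, 0.6)) == pytest.approx(0.09, abs=1e-15)
        assert float(ref_model.typical_v(0.93)) == pytest.approx(0.81, abs=1e-15)

    def test_volume_scales_linearly_with_weight(self, ref_model):
        assert float(ref_model.typical_v(0.465)) == pytest.approx(0.405, rel=1e-12)

    def test_creatinine_power_term(self, ref_model):
        # (0.6 / 0.15)^0.48 = 1.9452 relative to the reference creatinine
        base = float(ref_model.typical_cl(0.93, 0.6, pma=30.0))
        low_scr = float(ref_model.typical_cl(0.93, 0.15, pma=30.0))
        assert low_scr / base == pytest.approx(4.0**0.48, rel=1e-12)
        assert low_scr / base == pytest.approx(1.945, abs=1e-3)

    def test_monotonicity_in_covariates(self, ref_model):
        pma = np.linspace(22, 42, 30)
        cl = ref_model.typical_cl(1.0, 0.6, pma)
        assert np.all(np.diff(cl) > 0)
        wt = np.linspace(0.5, 2.0, 30)
        assert np.all(np.diff(ref_model.typical_cl(wt, 0.6, 30.0)) > 0)
        scr = np.linspace(0.2, 1.2, 30)
        assert np.all(np.diff(ref_model.typical_cl(1.0, scr, 30.0)) < 0)
        # volume does not depend on pma or creatinine
        assert float(ref_model.typical_v(1.0)) == float(ref_model.typical_v(1.0))

    def test_typical_parameters_profile(self, ref_model):
        cov = v.CovariateProfile("a", weight=0.93, pma=26.3, pna=10, scr=0.6)
        cl, vol = v.typical_parameters(cov, ref_model)
        assert cl == pytest.approx(0.045, rel=1e-12)  # half-mature at tma50
        assert vol == pytest.approx(0.81, rel=1e-12)

    def test_invalid_scr_rejected(self, ref_model):
        with pytest.raises(DomainError):
            ref_model.typical_cl(1.0, 0.0, 30.0)


class TestConcentrationProfile:
    def test_zero_before_first_infusion(self):
        params = v.IndividualParameters(cl=0.09, v=0.81)
        reg = v.Regimen(15, 12, n_doses=3)
        conc = v.concentration_profile(reg, params, [0.0], weight=1.0)
        assert conc[0] == 0.0

    def test_linearity_in_dose(self):
        params = v.IndividualParameters(cl=0.07, v=0.7)
        times = np.linspace(0.5, 36, 40)
        c1 = v.concentration_profile(v.Regimen(10, 12, n_doses=3), params, times, 1.0)
        c2 = v.concentration_profile(v.Regimen(20, 12, n_doses=3), params, times, 1.0)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_matches_runge_kutta_oracle(self):
        cl, vol, tinf = 0.09, 0.81, 1.0
        params = v.IndividualParameters(cl=cl, v=vol)
        reg = v.Regimen(15.0 / 0.93, 12, n_doses=3)  # 15 mg doses at 0.93 kg
        times = np.array([0.5, 1.0, 2.0, 6.0, 12.0, 13.5, 20.0, 30.0])
        analytic = v.concentration_profile(reg, params, times, weight=0.93)
        numeric = ode_oracle(times, [0.0, 12.0, 24.0], 15.0, cl, vol, tinf)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-3)

    def test_negative_times_rejected(self):
        params = v.IndividualParameters(cl=0.09, v=0.81)
        with pytest.raises(DomainError):
            v.concentration_profile(v.Regimen(15, 12), params, [-1.0], 1.0)


class TestSteadyState:
    def test_auc_identity(self):
        m = v.steady_state_metrics(v.Regimen(15, 12), cl=0.075, v=0.7, weight=1.0)
        assert float(m.auc24) == pytest.approx(400.0, rel=1e-12)
        m2 = v.steady_state_metrics(v.Regimen(17.5, 12), cl=0.09, v=0.81, weight=0.93)
        assert float(m2.auc24) == pytest.approx(361.67, abs=0.01)

    def test_trough_vanishes_for_long_intervals(self):
        m = v.steady_state_metrics(v.Regimen(15, 2000, infusion_duration=1.0),
                                   cl=0.09, v=0.81, weight=1.0)
        assert float(m.trough) < 1e-6

    def test_limit_of_dose_superposition(self):
        # analytic steady state equals the accumulated finite course after
        # >= 15 half-lives, within 0.1%
        cl, vol, wt, tau = 0.06, 0.72, 0.9, 12.0
        ke = cl / vol
        n = int(np.ceil(15 * np.log(2) / ke / tau)) + 1
        reg = v.Regimen(15, tau, n_doses=n)
        params = v.IndividualParameters(cl=cl, v=vol)
        t0 = (n - 1) * tau
        sup = v.concentration_profile(reg, params, [t0 + tau - 0.5, t0 + 2.0], wt)
        ss_trough = steady_state_concentration(tau - 0.5, 15 * wt, tau, 1.0, cl, vol)
        ss_peak = steady_state_concentration(2.0, 15 * wt, tau, 1.0, cl, vol)
        assert sup[0] == pytest.approx(float(ss_trough), rel=1e-3)
        assert sup[1] == pytest.approx(float(ss_peak), rel=1e-3)

    def test_auc_against_trapezoidal_integration(self):
        cl, vol, wt = 0.05, 0.65, 0.8
        reg = v.Regimen(15, 12)
        grid = np.arange(0.0, 24.0 + 1e-9, 0.005)
        conc = steady_state_concentration(np.mod(grid, 12.0), 15 * wt, 12.0, 1.0, cl, vol)
        trap = np.trapezoid(conc, grid)
        m = v.steady_state_metrics(reg, cl, vol, wt)
        assert float(m.auc24) == pytest.approx(trap, rel=5e-3)

    def test_invalid_parameters(self):
        with pytest.raises(DomainError):
            v.steady_state_metrics(v.Regimen(15, 12), cl=-0.1, v=0.8, weight=1.0)
        with pytest.raises(ConfigurationError):
            v.Regimen(15, 12, infusion_duration=12.0)


class TestInitiationExposure:
    """Early-treatment (pre-steady-state) exposure of a course started at t=0."""

    def test_auc_matches_trapezoidal_integration(self):
        cl, vol, wt = 0.05, 0.65, 0.8
        reg = v.Regimen(15, 12)
        m = initiation_exposure_metrics(reg, cl, vol, wt)
        grid = np.arange(24.0, 48.0 + 1e-9, 0.002)
        conc = infusion_concentration(grid, [0, 12, 24, 36], 15 * wt, cl, vol, 1.0)
        assert float(m.auc24) == pytest.approx(np.trapezoid(conc, grid), rel=2e-3)

    def test_trough_is_first_monitoring_occasion(self):
        cl, vol, wt = 0.05, 0.65, 0.8
        for tau, t_tr in [(12.0, 23.5), (18.0, 35.5), (24.0, 23.5), (8.0, 23.5)]:
            m = initiation_exposure_metrics(v.Regimen(15, tau), cl, vol, wt)
            starts = np.arange(0.0, t_tr + 1.0, tau)
            expect = infusion_concentration([t_tr], starts, 15 * wt, cl, vol, 1.0)[0]
            assert float(m.trough) == pytest.approx(expect, rel=1e-12), tau

    def test_below_steady_state(self):
        # accumulating concentrations: initiation exposure < steady state
        cl, vol, wt = 0.04, 0.7, 0.8
        reg = v.Regimen(15, 12)
        early = initiation_exposure_metrics(reg, cl, vol, wt)
        ss = v.steady_state_metrics(reg, cl, vol, wt)
        assert float(early.auc24) < float(ss.auc24)
        assert float(early.trough) < float(ss.trough)

    def test_invalid_window(self):
        with pytest.raises(ConfigurationError):
            initiation_exposure_metrics(v.Regimen(15, 12), 0.05, 0.7, 1.0,
                                        window=(48.0, 24.0))


class TestScrConversion:
    @pytest.mark.parametrize("enz,expected", [(0.0, 0.122), (1.05, 1.122), (0.903, 0.982)])
    def test_linear_calibration(self, enz, expected):
        assert v.convert_scr_enzymatic_to_jaffe(enz) == pytest.approx(expected, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            v.convert_scr_enzymatic_to_jaffe(-0.1)


class TestDomainTypes:
    def test_covariate_profile_invariants(self):
        with pytest.raises(DomainError):
            v.CovariateProfile("x", weight=-1, pma=30, pna=5, scr=0.6)
        with pytest.raises(DomainError):
            v.CovariateProfile("x", weight=1, pma=50, pna=5, scr=0.6)
        with pytest.raises(DomainError):
            v.CovariateProfile("x", weight=1, pma=28, pna=5, scr=0.6, ga=30)

    def test_individual_parameters_exponential_link(self):
        p = v.IndividualParameters.from_typical(0.09, 0.81, eta_cl=-0.2, eta_v=0.1)
        assert p.cl == pytest.approx(0.09 * np.exp(-0.2), rel=1e-12)
        assert p.v == pytest.approx(0.81 * np.exp(0.1), rel=1e-12)

    def test_error_model_validation(self):
        with pytest.raises(ConfigurationError):
            v.PopulationModel(error_model="constant", resid_a=0.0)
        m = v.PopulationModel(error_model="combined", resid_a=0.5)
        sd = m.residual_sd(10.0)
        assert float(sd) == pytest.approx(np.hypot(0.5, 3.0), rel=1e-12)
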