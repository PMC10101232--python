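"""Synthetic cohort: marginals, reference dosing, sampling design, splitting."""

import numpy as np
import pandas as pd
import pytest

import vancoppk as v
from vancoppk._design import build_design, predicted_concentration
from vancoppk.errors import ConfigurationError, DataError, DomainError


@pytest.fixture(scope="module")
def big():
    return v.sample_covariates(v.CohortSpec(n=10_000, seed=5))


class TestCovariateSampling:

    def test_marginal_moments_reproduce_targets(self, big):
        assert big["weight"].mean() == pytest.approx(1.0, abs=0.01)
        assert big["weight"].std() == pytest.approx(0.29, abs=0.01)
        assert big["pma"].mean() == pytest.approx(30.0, abs=0.1)
        assert big["pma"].std() == pytest.approx(3.2, abs=0.1)
        assert big["scr"].mean() == pytest.approx(0.64, abs=0.01)
        assert big["scr"].std() == pytest.approx(0.22, abs=0.01)

    def test_truncation_ranges_respected(self, big):
        assert big["weight"].between(0.46, 2.2).all()
        assert big["pma"].between(22, 42).all()
        assert big["scr"].between(0.2, 1.2).all()
        assert big["birth_weight"].between(0.46, 1.5).all()

    def test_elbw_fraction_near_study_value(self, big):
        # extremely-low-birth-weight fraction close to the study's 58%
        assert big["elbw"].mean() == pytest.approx(0.58, abs=0.05)

    def test_latent_dependence_structure(self, big):
        assert np.corrcoef(big.weight, big.pma)[0, 1] > 0.6
        assert np.corrcoef(big.pma, big.scr)[0, 1] < -0.1
        assert np.corrcoef(big.weight, big.birth_weight)[0, 1] > 0.8

    def test_deterministic_given_seed(self):
        a = v.sample_covariates(v.CohortSpec(n=50, seed=9))
        b = v.sample_covariates(v.CohortSpec(n=50, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort(self):
        assert len(v.sample_covariates(v.CohortSpec(n=0))) == 0

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            v.CohortSpec(weight_mean=3.0)  # outside [0.46, 2.2]

    def test_non_positive_definite_copula_rejected(self):
        spec = v.CohortSpec(copula_corr=((1, 0.99, 0.99), (0.99, 1, -0.99),
                                         (0.99, -0.99, 1)))
        with pytest.raises(ConfigurationError):
            spec.latent_corr()

    def test_ga_derived_from_pma_and_pna(self, big):
        np.testing.assert_allclose(big["ga"], big["pma"] - big["pna"] / 7.0)


class TestScrStandardisation:
    def test_enzymatic_values_converted_exactly_once(self):
        df = v.sample_covariates(v.CohortSpec(n=200, seed=3))
        enz = df["scr_assay"] == "enzymatic"
        assert enz.any() and (~enz).any()
        np.testing.assert_allclose(
            df.loc[enz, "scr"],
            v.convert_scr_enzymatic_to_jaffe(df.loc[enz, "scr_measured"].to_numpy()),
        )
        np.testing.assert_allclose(df.loc[~enz, "scr"], df.loc[~enz, "scr_measured"])
        with pytest.raises(ValueError, match="twice"):
            v.standardize_scr(df)  # idempotence guard


class TestReferenceRegimens:
    @staticmethod
    def _cov(pma, pna, scr=0.6, ga=None):
        return v.CovariateProfile("x", weight=1.0, pma=pma, pna=pna, scr=scr, ga=ga)

    @pytest.mark.parametrize("pma,pna,dose,interval", [
        (28, 10, 15.0, 18.0),
        (28, 20, 15.0, 12.0),
        (33, 10, 15.0, 12.0),
        (33, 20, 15.0, 8.0),
        (38, 5, 15.0, 12.0),
        (38, 10, 15.0, 8.0),
        (46, 3, 15.0, 6.0),
    ])
    def test_neofax_bands(self, pma, pna, dose, interval):
        reg = v.reference_regimen(self._cov(pma, pna), "neofax")
        assert (reg.dose_per_kg, reg.interval) == (dose, interval)

    @pytest.mark.parametrize("pma,pna,interval", [
        (28, 10, 18.0), (28, 25, 12.0), (33, 20, 8.0), (40, 3, 12.0),
    ])
    def test_lexicomp_age_bands(self, pma, pna, interval):
        reg = v.reference_regimen(self._cov(pma, pna), "lexicomp_age")
        assert reg.interval == interval

    @pytest.mark.parametrize("ga,scr,dose,interval", [
        (27, 0.9, 15.0, 24.0),
        (27, 0.4, 15.0, 12.0),
        (27, 0.6, 20.0, 24.0),
        (30, 0.8, 20.0, 24.0),
        (30, 1.1, 15.0, 24.0),
    ])
    def test_lexicomp_renal_bands(self, ga, scr, dose, interval):
        reg = v.reference_regimen(self._cov(30, 5, scr=scr, ga=ga), "lexicomp_renal")
        assert (reg.dose_per_kg, reg.interval) == (dose, interval)

    def test_renal_dosing_requires_ga(self):
        with pytest.raises(DomainError):
            v.reference_regimen(self._cov(30, 5), "lexicomp_renal")

    def test_unknown_reference(self):
        with pytest.raises(ConfigurationError):
            v.reference_regimen(self._cov(30, 5), "nonsense")


class TestSimulatedObservations:
    def test_noise_free_simulation_equals_model_prediction(self):
        m0 = v.PopulationModel(omega_cl=0.0, omega_v=0.0, resid_b=0.0)
        cohort = v.sample_cohort(v.CohortSpec(n=25, seed=2))
        table = v.simulate_observations(cohort, m0, seed=4)
        d = build_design(table)
        f = predicted_concentration(
            d, np.asarray(m0.typical_cl(d.weight, d.scr, d.pma)),
            np.asarray(m0.typical_v(d.weight)))
        np.testing.assert_allclose(f, d.y, rtol=1e-12)

    def test_trough_times_precede_a_scheduled_dose_by_30_min(self, small_table):
        for sid, sub in small_table.iter_subjects():
            doses = set(sub[sub.EVID == 1]["TIME"])
            troughs = [t for t in sub[sub.EVID == 0]["TIME"]
                       if any(abs(t + 0.5 - d) < 1e-9 for d in doses)]
            assert troughs, f"subject {sid} has no trough aligned to a dose"

    def test_observation_count_with_second_trough_fraction(self):
        # 162 subjects, 32% second troughs, no peaks -> about 214 observations
        design = v.SamplingDesign(second_trough_fraction=0.32, peak_fraction=0.0)
        cohort = v.sample_cohort(v.CohortSpec(n=162, seed=8))
        table = v.simulate_observations(cohort, v.PopulationModel(), design, seed=14)
        assert abs(table.n_observations - 214) <= 20

    def test_deterministic_given_seed(self, small_cohort, ref_model):
        a = v.simulate_observations(small_cohort, ref_model, seed=99)
        b = v.simulate_observations(small_cohort, ref_model, seed=99)
        assert a == b

    def test_observed_variance_inflates_with_residual_error(self):
        # Var(y) ~ f^2 (e^{w^2}-1 + b^2 e^{w^2}): check the Monte Carlo ordering
        # and magnitude against the moment approximation for one covariate point
        cov = [v.CovariateProfile(i, weight=1.0, pma=30.0, pna=10, scr=0.6)
               for i in range(4000)]
        out = []
        for b in (0.1, 0.6):
            m = v.PopulationModel(resid_b=b)
            design = v.SamplingDesign(second_trough_fraction=0, peak_fraction=0)
            table = v.simulate_observations(cov, m, design, seed=31)
            y = table.observations()["DV"].to_numpy()
            f = y.mean()
            w = m.omega_cl
            approx = f**2 * (np.exp(w**2) - 1 + b**2 * np.exp(w**2))
            out.append((y.var(), approx))
        (var_lo, approx_lo), (var_hi, approx_hi) = out
        assert var_lo < var_hi
        assert var_hi == pytest.approx(approx_hi, rel=0.35)


class TestSplit:
    def test_split_sizes_and_disjointness(self, small_table):
        train, valid = v.split_dataset(small_table, 0.7, seed=3)
        assert train.n_subjects == 21 and valid.n_subjects == 9
        assert not set(train.subject_ids) & set(valid.subject_ids)
        assert set(train.subject_ids) | set(valid.subject_ids) == set(small_table.subject_ids)
        # split is by subject: each subject's rows stay together
        assert len(train) + len(valid) == len(small_table)

    def test_deterministic(self, small_table):
        a = v.split_dataset(small_table, 0.7, seed=12)[0]
        b = v.split_dataset(small_table, 0.7, seed=12)[0]
        assert a.subject_ids == b.subject_ids

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, small_table, fraction):
        with pytest.raises(ConfigurationError):
            v.split_dataset(small_table, fraction, seed=1)
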