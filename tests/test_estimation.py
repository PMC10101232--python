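"""Mixed-effects estimation: recovery limits, EBEs, LRT, RSE, invariances."""

import numpy as np
import pandas as pd
import pytest

import vancoppk as v
from vancoppk._design import build_design
from vancoppk.errors import ConfigurationError
from vancoppk.estimation import (
    ModelStructure,
    _LaplaceProblem,
    _params_from_model,
    compute_rse,
    estimate_ebe,
    fit_population,
    lrt_step,
)


def _simulate(n, model, seed, design=None):
    cohort = v.sample_cohort(v.CohortSpec(n=n, seed=seed))
    return v.simulate_observations(cohort, model, design=design, seed=seed + 1000)


class TestFit:
    def test_noiseless_identifiable_limit(self):
        # zero IIV, (almost) zero residual noise, peaks on every subject:
        # cl_ref and v_ref must come back at optimizer tolerance
        gen = v.PopulationModel(omega_cl=0.0, omega_v=0.0, resid_b=0.0)
        design = v.SamplingDesign(second_trough_fraction=1.0, peak_fraction=1.0)
        table = _simulate(20, gen, seed=5, design=design)
        start = v.PopulationModel(cl_ref=0.06, v_ref=0.6, omega_cl=0.05,
                                  omega_v=0.05, resid_b=0.05)
        structure = ModelStructure(init=start, free=("cl_ref", "v_ref"))
        fit = fit_population(table, structure, seed=0)
        assert fit.converged
        assert fit.estimates.cl_ref == pytest.approx(0.09, rel=0.02)
        assert fit.estimates.v_ref == pytest.approx(0.81, rel=0.05)

    def test_omitting_active_covariate_raises_ofv(self):
        # nested-model likelihood ordering on creatinine-driven data
        table = _simulate(80, v.PopulationModel(), seed=17)
        full = fit_population(table, ModelStructure(), seed=1, maxfev=1500)
        reduced = fit_population(table, ModelStructure(include_scr=False),
                                 seed=1, maxfev=1500)
        assert full.ofv < reduced.ofv

    def test_generating_model_beats_misspecified_submodel_in_ofv(self):
        # objective-level check on a large fixture (>= 1,000 observations)
        table = _simulate(720, v.PopulationModel(), seed=29)
        assert table.n_observations >= 1000
        design = build_design(table)
        problem = _LaplaceProblem(design, ModelStructure())
        truth = _params_from_model(v.PopulationModel())
        miss = dict(truth, scr_exp=0.0)
        assert problem.ofv(truth) < _LaplaceProblem(
            build_design(table), ModelStructure()).ofv(miss)

    def test_objective_invariant_to_subject_order(self):
        table = _simulate(25, v.PopulationModel(), seed=3)
        df = table.data
        order = list(pd.unique(df["ID"]))[::-1]
        shuffled = v.EventTable(
            pd.concat([df[df.ID == sid] for sid in order], ignore_index=True),
        )
        p = _params_from_model(v.PopulationModel())
        a = _LaplaceProblem(build_design(table), ModelStructure()).ofv(p)
        b = _LaplaceProblem(build_design(shuffled), ModelStructure()).ofv(p)
        assert a == pytest.approx(b, abs=1e-6)

    def test_degenerate_data_flagged_not_raised(self):
        table = _simulate(6, v.PopulationModel(), seed=7)
        df = table.data.copy()
        df.loc[df.EVID == 0, "DV"] = 12.0
        fit = fit_population(v.EventTable(df), ModelStructure(), seed=0, maxfev=150)
        assert not fit.converged
        assert "degenerate" in fit.message


class TestEBE:
    @pytest.fixture(scope="class")
    def one_subject(self):
        rows = []
        common = {"ID": 1, "WT": 1.0, "PMA": 30.0, "PNA": 10.0, "GA": 28.6,
                  "SCR": 0.6, "SEX": "male"}
        for k in range(9):
            rows.append({**common, "TIME": 12.0 * k, "EVID": 1, "AMT": 15.0,
                         "RATE": 15.0, "DV": np.nan})
        return rows

    def _table(self, rows, dv):
        obs = {"ID": 1, "WT": 1.0, "PMA": 30.0, "PNA": 10.0, "GA": 28.6,
               "SCR": 0.6, "SEX": "male", "TIME": 95.5, "EVID": 0,
               "AMT": np.nan, "RATE": np.nan, "DV": dv}
        df = pd.DataFrame(rows + [obs]).sort_values("TIME", kind="stable")
        return v.EventTable(df)

    def test_no_observations_returns_prior_mode(self, ref_model, one_subject):
        table = v.EventTable(pd.DataFrame(one_subject), validate=False)
        p = estimate_ebe(table, ref_model)
        assert p.eta_cl == 0.0 and p.eta_v == 0.0

    def test_observation_at_typical_prediction_gives_near_zero_etas(
            self, ref_model, one_subject):
        typ = self._typical_trough(ref_model)
        p = estimate_ebe(self._table(one_subject, typ), ref_model)
        # not exactly zero: under proportional error the log-SD term shifts
        # the conditional mode slightly off the exact-fit point
        assert abs(p.eta_cl) < 0.06 and abs(p.eta_v) < 0.06

    def test_high_trough_implies_lower_clearance(self, ref_model, one_subject):
        typ = self._typical_trough(ref_model)
        p = estimate_ebe(self._table(one_subject, 2 * typ), ref_model)
        assert p.eta_cl < -0.05

    def test_mode_matches_grid_search_oracle(self, ref_model, one_subject):
        # brute-force the conditional objective over an eta grid
        table = self._table(one_subject, 15.0)
        p = estimate_ebe(table, ref_model)
        design = build_design(table)
        problem = _LaplaceProblem(design, ModelStructure(init=ref_model))
        g = problem._gfun(*problem._unpack(_params_from_model(ref_model)))
        grid = np.linspace(-1.0, 1.0, 81)
        best, arg = np.inf, None
        for e1 in grid:
            etas = np.column_stack([np.full_like(grid, e1), grid])
            vals = np.array([g(np.array([[e1, e2]]))[0] for e2 in grid])
            if vals.min() < best:
                best, arg = vals.min(), (e1, grid[vals.argmin()])
        assert p.eta_cl == pytest.approx(arg[0], abs=0.05)
        assert p.eta_v == pytest.approx(arg[1], abs=0.05)

    def test_shrinkage_grows_with_residual_noise(self):
        # EBE spread shrinks toward the prior as b rises
        spreads = []
        for b in (0.1, 0.3, 0.6):
            gen = v.PopulationModel(resid_b=b)
            table = _simulate(300, gen, seed=23)
            design = build_design(table)
            problem = _LaplaceProblem(design, ModelStructure(init=gen))
            eta = problem.ebes(_params_from_model(gen))
            spreads.append(eta[:, 0].std())
        assert spreads[0] > spreads[1] > spreads[2]

    @staticmethod
    def _typical_trough(model):
        cl = float(model.typical_cl(1.0, 0.6, 30.0))
        vol = float(model.typical_v(1.0))
        return float(v.infusion_concentration(
            [95.5], np.arange(9) * 12.0, 15.0, cl, vol, 1.0)[0])


class TestLRT:
    def test_zero_improvement_excluded(self):
        a = _dummy_fit(ofv=100.0)
        b = _dummy_fit(ofv=100.0)
        res = lrt_step(a, b, df=1)
        assert res.p_value == 1.0 and not res.include

    def test_chi_square_threshold(self):
        res = lrt_step(_dummy_fit(ofv=96.15), _dummy_fit(ofv=100.0), df=1)
        assert res.p_value < 0.05 and res.include
        res2 = lrt_step(_dummy_fit(ofv=96.2), _dummy_fit(ofv=100.0), df=1)
        assert res2.p_value > 0.05 and not res2.include

    def test_negative_delta_warns_and_excludes(self):
        with pytest.warns(UserWarning):
            res = lrt_step(_dummy_fit(ofv=105.0), _dummy_fit(ofv=100.0), df=1)
        assert not res.include and res.warning is not None


class TestRSE:
    def test_zero_bootstrap_replicates_rejected(self):
        table = _simulate(10, v.PopulationModel(), seed=2)
        fit = fit_population(table, ModelStructure(free=("cl_ref",)), seed=0,
                             maxfev=100)
        with pytest.raises(ConfigurationError):
            compute_rse(fit, method="bootstrap", n_boot=0)

    def test_standard_error_scales_with_sample_size(self):
        # doubling every subject shrinks the (Fisher) RSE by about 1/sqrt(2)
        structure = ModelStructure(free=("cl_ref", "v_ref", "omega_cl", "resid_b"))
        table = _simulate(60, v.PopulationModel(), seed=13)
        fit1 = fit_population(table, structure, seed=0, maxfev=1200)
        df = table.data
        dup = df.copy()
        dup["ID"] = dup["ID"].astype(int) + 10_000
        big = v.EventTable(pd.concat([df, dup], ignore_index=True))
        fit2 = fit_population(big, structure, seed=0, maxfev=1200)
        r1 = compute_rse(fit1, method="fisher")
        r2 = compute_rse(fit2, method="fisher")
        ratio = r2["cl_ref"] / r1["cl_ref"]
        assert 0.5 < ratio < 0.9


def _dummy_fit(ofv):
    return v.FitResult(
        estimates=v.PopulationModel(), ofv=ofv, converged=True, n_obs=10,
        n_subjects=5, free_names=("cl_ref",), ebes=pd.DataFrame(),
    )
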