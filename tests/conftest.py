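import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vancoppk as v

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_model() -> v.PopulationModel:
    """The reference VLBW population model (package defaults)."""
    return v.PopulationModel()


@pytest.fixture(scope="session")
def small_cohort():
    return v.sample_cohort(v.CohortSpec(n=30, seed=11))


@pytest.fixture(scope="session")
def small_table(ref_model, small_cohort) -> v.EventTable:
    """A 30-subject sparse monitoring dataset simulated from the reference model."""
    return v.simulate_observations(small_cohort, ref_model, seed=21)


def ode_oracle(times, dose_times, dose_mg, cl, vol, tinf):
    """Runge-Kutta integration of dC/dt = rate_in/V - (Cl/V) C (independent oracle)."""
    from scipy.integrate import solve_ivp

    times = np.atleast_1d(np.asarray(times, float))

    def rate_in(t):
        return sum(dose_mg / tinf for s in dose_times if s <= t < s + tinf)

    def rhs(t, y):
        return [(rate_in(t) - cl * y[0]) / vol]

    t_end = float(max(times.max(), max(dose_times) + tinf)) + 1e-9
    sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=times,
                    max_step=0.02, rtol=1e-9, atol=1e-12)
    return sol.y[0]
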