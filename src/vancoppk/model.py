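"""Structural and covariate pharmacokinetic model for vancomycin in
very-low-birth-weight (VLBW) neonates.

The disposition model is a one-compartment system with zero-order input
(intravenous infusion) and first-order elimination.  Typical (population)
parameters are predicted from covariates:

* volume of distribution scales linearly with body weight
  (``V = v_ref * (weight / 0.93)``),
* clearance scales allometrically with weight (fixed exponent 0.75),
  decreases with serum creatinine through a power term with exponent
  ``scr_exp`` on ``(0.6 / Scr)``, and matures with postmenstrual age (PMA)
  through a sigmoidal Hill function
  ``F(PMA) = PMA^hill / (PMA^hill + TMA50^hill)``, where ``TMA50`` is the
  PMA at which clearance reaches half its mature value.

Between-subject variability is lognormal (``p_i = p * exp(eta_i)``) and the
residual error is proportional by default (``y = f * (1 + b * eps)``), with
constant and combined alternatives available.

Default parameter values are the package's reference estimates for a VLBW
neonatal population (reference weight 0.93 kg, reference creatinine
0.6 mg/dl); they can be overridden field by field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DomainError

__all__ = [
    "REF_WEIGHT_KG",
    "REF_SCR_MGDL",
    "CovariateProfile",
    "PopulationModel",
    "IndividualParameters",
    "Regimen",
    "ExposureMetrics",
    "maturation_fraction",
    "typical_parameters",
    "concentration_profile",
    "infusion_concentration",
    "steady_state_concentration",
    "steady_state_metrics",
    "initiation_exposure_metrics",
    "convert_scr_enzymatic_to_jaffe",
]

#: Reference (median) body weight of the modelled population, kg.
REF_WEIGHT_KG = 0.93
#: Reference serum creatinine, mg/dl (Jaffe scale).
REF_SCR_MGDL = 0.6

_PMA_BOUNDS = (20.0, 48.0)
_SEX_LEVELS = ("male", "female", "missing")


def _as_float_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, (arr.ndim == 0)


def maturation_fraction(pma, hill: float = 4.42, tma50: float = 26.3):
    """Sigmoidal maturation of clearance with postmenstrual age.

    Returns ``pma**hill / (pma**hill + tma50**hill)``, evaluated on the log
    scale for numerical stability.  The function is strictly increasing in
    ``pma``, equals 0.5 exactly at ``pma == tma50`` and tends to 1 as
    ``pma -> inf`` (``numpy.inf`` is accepted and returns 1.0).

    Parameters
    ----------
    pma : float or array-like
        Postmenstrual age in weeks; must be positive.
    hill : float
        Hill coefficient (dimensionless, > 0).
    tma50 : float
        PMA in weeks at which clearance is 50% of the mature value (> 0).
    """
    if not hill > 0:
        raise DomainError(f"hill must be positive, got {hill}")
    if not tma50 > 0:
        raise DomainError(f"tma50 must be positive, got {tma50}")
    arr, scalar = _as_float_array(pma)
    if np.any(~(arr > 0)):
        raise DomainError("pma must be positive")
    with np.errstate(divide="ignore"):
        frac = expit(hill * (np.log(arr) - math.log(tma50)))
    return float(frac) if scalar else frac


def convert_scr_enzymatic_to_jaffe(enzymatic):
    """Convert an enzymatic-assay serum creatinine (mg/dl) to the Jaffe scale.

    The covariate model is parameterised on the Jaffe scale; creatinine
    measured with an enzymatic assay is rescaled with the linear calibration
    ``jaffe = 0.122 + enzymatic / 1.05``.
    """
    arr, scalar = _as_float_array(enzymatic)
    if np.any(arr < 0):
        raise DomainError("enzymatic creatinine must be non-negative")
    out = 0.122 + arr / 1.05
    return float(out) if scalar else out


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline covariates of one neonate.

    ``scr`` is on the Jaffe scale (convert enzymatic measurements first with
    :func:`convert_scr_enzymatic_to_jaffe`).  ``elbw`` flags extremely low
    birth weight (birth weight < 1.0 kg).
    """

    subject_id: int | str
    weight: float
    pma: float
    pna: float
    scr: float
    ga: float | None = None
    sex: str = "missing"
    elbw: bool | None = None
    birth_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise DomainError(f"subject {self.subject_id}: weight must be > 0")
        if not self.scr > 0:
            raise DomainError(f"subject {self.subject_id}: scr must be > 0")
        if not (_PMA_BOUNDS[0] <= self.pma <= _PMA_BOUNDS[1]):
            raise DomainError(
                f"subject {self.subject_id}: pma {self.pma} outside model range "
                f"{_PMA_BOUNDS}"
            )
        if self.pna < 0:
            raise DomainError(f"subject {self.subject_id}: pna must be >= 0")
        if self.ga is not None and self.pma + 1e-9 < self.ga:
            raise DomainError(
                f"subject {self.subject_id}: pma ({self.pma}) < ga ({self.ga})"
            )
        if self.sex not in _SEX_LEVELS:
            raise DomainError(
                f"subject {self.subject_id}: sex must be one of {_SEX_LEVELS}"
            )


@dataclass(frozen=True)
class PopulationModel:
    """Population (fixed-effect and variability) parameters.

    Defaults are the reference VLBW estimates: clearance 0.09 L/h at the
    mature limit for a 0.93 kg neonate with creatinine 0.6 mg/dl, volume
    0.81 L at 0.93 kg, Hill coefficient 4.42, TMA50 26.3 weeks, creatinine
    exponent 0.48, lognormal between-subject SDs 0.28 (Cl) and 0.24 (V) and
    proportional residual SD 0.3.
    """

    cl_ref: float = 0.09
    v_ref: float = 0.81
    hill: float = 4.42
    tma50: float = 26.3
    scr_exp: float = 0.48
    wt_exp_cl: float = 0.75
    wt_exp_v: float = 1.0
    ref_weight: float = REF_WEIGHT_KG
    ref_scr: float = REF_SCR_MGDL
    omega_cl: float = 0.28
    omega_v: float = 0.24
    resid_b: float = 0.3
    resid_a: float = 0.0
    error_model: str = "proportional"
    maturation: bool = True

    def __post_init__(self) -> None:
        for name in ("cl_ref", "v_ref", "ref_weight", "ref_scr"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        for name in ("hill", "tma50"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        for name in ("omega_cl", "omega_v", "resid_b", "resid_a"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.error_model not in ("proportional", "constant", "combined"):
            raise ConfigurationError(
                f"unknown error model {self.error_model!r}"
            )
        if self.error_model in ("constant", "combined") and self.resid_a == 0:
            raise ConfigurationError(
                f"error model {self.error_model!r} requires resid_a > 0"
            )

    # -- typical-value predictions -------------------------------------
    def typical_v(self, weight):
        """Typical volume of distribution (L) at a given weight (kg)."""
        return self.v_ref * (np.asarray(weight, float) / self.ref_weight) ** self.wt_exp_v

    def typical_cl(self, weight, scr, pma=None):
        """Typical clearance (L/h).

        ``pma=None`` evaluates the mature limit (maturation fraction 1);
        otherwise the sigmoidal maturation term is applied.
        """
        scr_arr = np.asarray(scr, float)
        if np.any(~(scr_arr > 0)):
            raise DomainError("scr must be positive")
        wt = np.asarray(weight, float)
        cl = (
            self.cl_ref
            * (wt / self.ref_weight) ** self.wt_exp_cl
            * (self.ref_scr / scr_arr) ** self.scr_exp
        )
        if self.maturation and pma is not None:
            cl = cl * maturation_fraction(pma, self.hill, self.tma50)
        return cl

    def residual_sd(self, f):
        """Residual-error SD at prediction ``f`` under the configured model."""
        f = np.asarray(f, float)
        if self.error_model == "proportional":
            return self.resid_b * np.abs(f)
        if self.error_model == "constant":
            return self.resid_a * np.ones_like(f)
        return np.sqrt(self.resid_a**2 + (self.resid_b * f) ** 2)

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


def typical_parameters(cov: CovariateProfile, model: PopulationModel) -> tuple[float, float]:
    """Typical (clearance L/h, volume L) for one covariate profile."""
    cl = float(model.typical_cl(cov.weight, cov.scr, cov.pma))
    v = float(model.typical_v(cov.weight))
    return cl, v


@dataclass(frozen=True)
class IndividualParameters:
    """Individual parameters ``p_i = p_typical * exp(eta_i)``."""

    cl: float
    v: float
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise DomainError("individual cl and v must be positive")

    @classmethod
    def from_typical(
        cls, typical_cl: float, typical_v: float, eta_cl: float = 0.0, eta_v: float = 0.0
    ) -> "IndividualParameters":
        return cls(
            cl=typical_cl * math.exp(eta_cl),
            v=typical_v * math.exp(eta_v),
            eta_cl=eta_cl,
            eta_v=eta_v,
        )


@dataclass(frozen=True)
class Regimen:
    """Repeated intravenous-infusion regimen on a mg/kg basis.

    ``n_doses`` is either a positive integer (finite course starting at
    time 0, one dose every ``interval`` hours) or ``"steady_state"``.
    The default infusion duration is 1 h.
    """

    dose_per_kg: float
    interval: float
    infusion_duration: float = 1.0
    n_doses: int | str = "steady_state"

    def __post_init__(self) -> None:
        if not self.dose_per_kg > 0:
            raise ConfigurationError("dose_per_kg must be positive")
        if not self.interval > 0:
            raise ConfigurationError("interval must be positive")
        if not 0 < self.infusion_duration < self.interval:
            raise ConfigurationError(
                "infusion_duration must lie strictly between 0 and the dosing interval "
                f"(got {self.infusion_duration} h with interval {self.interval} h)"
            )
        if self.n_doses != "steady_state":
            if not (isinstance(self.n_doses, (int, np.integer)) and self.n_doses >= 1):
                raise ConfigurationError(
                    'n_doses must be a positive integer or "steady_state"'
                )

    def dose_mg(self, weight):
        return self.dose_per_kg * np.asarray(weight, float)

    @property
    def daily_dose_per_kg(self) -> float:
        return self.dose_per_kg * 24.0 / self.interval

    @property
    def label(self) -> str:
        return f"{self.dose_per_kg:g} mg/kg q{self.interval:g}h"


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary for one subject under one regimen.

    ``auc24`` is the area under the curve over 24 h at steady state
    (ug*h/ml); ``trough`` the concentration at the end of a dosing interval;
    ``peak`` the concentration 1 h after the end of the infusion (the
    therapeutic-drug-monitoring sampling convention, not Cmax).
    Fields may hold arrays when computed in vectorised form.
    """

    auc24: float | np.ndarray
    trough: float | np.ndarray
    peak: float | np.ndarray


# ---------------------------------------------------------------------------
# concentration-time solutions
# ---------------------------------------------------------------------------

def infusion_concentration(times, dose_times, dose_mg, cl, v, infusion_duration):
    """Superposition solution for repeated zero-order infusions.

    Each dose of ``dose_mg`` mg is infused at constant rate over
    ``infusion_duration`` h starting at the entries of ``dose_times``.
    Concentrations (ug/ml, i.e. mg/L) are returned at ``times`` (h).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    starts = np.atleast_1d(np.asarray(dose_times, dtype=float))
    ke = cl / v
    rate = dose_mg / infusion_duration
    dt = t[:, None] - starts[None, :]
    te = np.clip(dt, 0.0, infusion_duration)  # time infused so far
    td = np.clip(dt - infusion_duration, 0.0, None)  # decay time post infusion
    conc = (rate / cl) * (-np.expm1(-ke * te)) * np.exp(-ke * td)
    return conc.sum(axis=1)


def steady_state_concentration(t_in_interval, dose_mg, interval, infusion_duration, cl, v):
    """Closed-form steady-state concentration within one dosing interval.

    Uses the geometric-series accumulation of the single-dose infusion
    solution; ``t_in_interval`` is time since the start of the current
    infusion, in ``[0, interval]``.  All arguments broadcast.
    """
    t = np.asarray(t_in_interval, dtype=float)
    dose = np.asarray(dose_mg, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ke = cl / v
    rate = dose / infusion_duration
    acc = -np.expm1(-ke * interval)  # 1 - exp(-ke*tau)
    end_inf = -np.expm1(-ke * infusion_duration)
    ctrough = (rate / cl) * end_inf * np.exp(-ke * (interval - infusion_duration)) / acc
    during = ctrough * np.exp(-ke * t) + (rate / cl) * (-np.expm1(-ke * np.minimum(t, infusion_duration)))
    after = (ctrough * np.exp(-ke * infusion_duration) + (rate / cl) * end_inf) * np.exp(
        -ke * np.clip(t - infusion_duration, 0.0, None)
    )
    return np.where(t <= infusion_duration, during, after)


def concentration_profile(
    regimen: Regimen,
    params: IndividualParameters,
    times: Sequence[float],
    weight: float,
):
    """Concentration-time profile for one individual under a regimen.

    For a finite ``n_doses`` the profile is the superposition of all
    administered infusions starting at time 0; for ``"steady_state"`` the
    times are interpreted modulo the dosing interval and evaluated with the
    closed-form steady-state solution.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    dose = float(regimen.dose_mg(weight))
    if regimen.n_doses == "steady_state":
        return np.asarray(
            steady_state_concentration(
                np.mod(t, regimen.interval),
                dose,
                regimen.interval,
                regimen.infusion_duration,
                params.cl,
                params.v,
            )
        )
    starts = np.arange(int(regimen.n_doses)) * regimen.interval
    return infusion_concentration(
        t, starts, dose, params.cl, params.v, regimen.infusion_duration
    )


def initiation_exposure_metrics(
    regimen: Regimen, cl, v, weight, window: tuple[float, float] = (24.0, 48.0)
) -> ExposureMetrics:
    """Early-treatment exposure for a dosing course started at time 0.

    This is the exposure an initial (pre-TDM) regimen delivers while
    concentrations are still accumulating: ``auc24`` is the exact analytic
    AUC over ``window`` (default the second day of therapy, hours 24-48,
    the period over which AUC-guided monitoring is evaluated when therapy
    starts), ``trough`` is drawn 30 min before the first dose at or after
    the window start (the first routine monitoring trough) and ``peak``
    1 h after the end of that dose's infusion.  The AUC uses the
    mass-balance identity ``AUC(w0, w1) = infused_mass(w0, w1)/Cl +
    (C(w0) - C(w1))/ke``, exact for linear elimination.  Accepts scalars or
    broadcastable arrays.
    """
    w0, w1 = window
    if not 0 <= w0 < w1:
        raise ConfigurationError("window must satisfy 0 <= start < end")
    cl_arr = np.asarray(cl, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(~(cl_arr > 0)) or np.any(~(v_arr > 0)):
        raise DomainError("cl and v must be positive")
    dose = np.asarray(regimen.dose_mg(weight), dtype=float)
    tau = regimen.interval
    tinf = regimen.infusion_duration
    rate = dose / tinf
    ke = cl_arr / v_arr
    starts = np.arange(0.0, w1, tau)

    def conc_at(t: float):
        total = np.zeros(np.broadcast(cl_arr, v_arr, dose).shape)
        for s in starts:
            dt = t - s
            if dt <= 0:
                continue
            te = min(dt, tinf)
            td = max(dt - tinf, 0.0)
            total = total + (rate / cl_arr) * (-np.expm1(-ke * te)) * np.exp(-ke * td)
        return total

    infused = np.zeros_like(dose, dtype=float)
    for s in starts:
        overlap = max(0.0, min(s + tinf, w1) - max(s, w0))
        if overlap > 0:
            infused = infused + rate * overlap
    auc = infused / cl_arr + (conc_at(w0) - conc_at(w1)) / ke

    later = starts[starts >= w0]
    t_ref = float(later[0]) if len(later) else w1
    trough = conc_at(t_ref - 0.5)
    peak = conc_at(t_ref + tinf + 1.0)
    return ExposureMetrics(auc24=auc, trough=trough, peak=peak)


def steady_state_metrics(regimen: Regimen, cl, v, weight) -> ExposureMetrics:
    """Steady-state exposure metrics from the closed-form solution.

    ``auc24 = (24 / interval) * dose_mg / cl`` exactly (linear elimination);
    for intervals that do not divide 24 h this is the time-averaged
    steady-state identity, which is what AUC-based dosing targets mean.
    ``trough`` is evaluated at the end of the interval and ``peak`` 1 h after
    the end of the infusion.  Accepts scalars or broadcastable arrays.
    """
    cl_arr = np.asarray(cl, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(~(cl_arr > 0)) or np.any(~(v_arr > 0)):
        raise DomainError("cl and v must be positive")
    dose = regimen.dose_mg(weight)
    auc24 = (24.0 / regimen.interval) * dose / cl_arr
    trough = steady_state_concentration(
        regimen.interval, dose, regimen.interval, regimen.infusion_duration, cl_arr, v_arr
    )
    peak_time = min(regimen.infusion_duration + 1.0, regimen.interval)
    peak = steady_state_concentration(
        peak_time, dose, regimen.interval, regimen.infusion_duration, cl_arr, v_arr
    )
    return ExposureMetrics(auc24=auc24, trough=trough, peak=peak)
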