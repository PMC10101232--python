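"""Synthetic VLBW neonatal cohorts and sparse therapeutic-drug-monitoring data.

The generator emulates the covariate structure of a multicentre VLBW
vancomycin cohort: truncated-normal marginals for current weight, PMA,
serum creatinine and birth weight, tied together by a Gaussian copula;
uniform postnatal age; gestational age derived as ``PMA - PNA/7``.
Marginal parameters are *realised* (post-truncation) moments: the
underlying normal parameters are moment-matched so that the sampled mean
and SD reproduce the targets despite truncation.

Dosing follows tertiary neonatal references (NeoFax-style PMA/PNA bands,
Lexicomp age- or kidney-function-directed bands), and sampling is
predominantly trough-only at steady state (30 min before a dose), with an
optional second trough and an occasional peak 1 h after the end of an
infusion, mirroring routine monitoring practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, truncnorm

from .errors import ConfigurationError, DataError, DomainError
from .events import EVENT_COLUMNS, EventTable
from .model import (
    CovariateProfile,
    PopulationModel,
    Regimen,
    convert_scr_enzymatic_to_jaffe,
    infusion_concentration,
)

__all__ = [
    "CohortSpec",
    "SamplingDesign",
    "sample_covariates",
    "sample_cohort",
    "standardize_scr",
    "reference_regimen",
    "simulate_observations",
    "split_dataset",
]


# ---------------------------------------------------------------------------
# cohort specification and covariate sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of the virtual cohort's covariate distribution.

    Defaults reproduce the pooled demographics of the modelled study
    population: weight 1.0 (SD 0.29) kg on [0.46, 2.2], PMA 30.0 (3.2) weeks
    on [22, 42], creatinine 0.64 (0.22) mg/dl on [0.2, 1.2] (Jaffe scale),
    birth weight 0.966 (0.27) kg on [0.46, 1.5], postnatal age uniform on
    1-30 days.  ``copula_corr`` is the latent correlation of
    (weight, pma, scr); birth weight is linked to the latent weight and PMA
    through ``bw_corr_weight`` / ``bw_corr_pma``.
    """

    n: int = 236
    weight_mean: float = 1.0
    weight_sd: float = 0.29
    weight_range: tuple[float, float] = (0.46, 2.2)
    pma_mean: float = 30.0
    pma_sd: float = 3.2
    pma_range: tuple[float, float] = (22.0, 42.0)
    scr_mean: float = 0.64
    scr_sd: float = 0.22
    scr_range: tuple[float, float] = (0.2, 1.2)
    birth_weight_mean: float = 0.966
    birth_weight_sd: float = 0.27
    birth_weight_range: tuple[float, float] = (0.46, 1.5)
    pna_range: tuple[int, int] = (1, 30)
    copula_corr: tuple = ((1.0, 0.7, 0.0), (0.7, 1.0, -0.2), (0.0, -0.2, 1.0))
    bw_corr_weight: float = 0.9
    bw_corr_pma: float = 0.6
    bw_corr_scr: float = 0.0
    sex_probs: tuple[float, float, float] = (0.46, 0.33, 0.21)  # male/female/missing
    enzymatic_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        for name in ("weight", "pma", "scr", "birth_weight"):
            mean = getattr(self, f"{name}_mean")
            lo, hi = getattr(self, f"{name}_range")
            if not lo < hi:
                raise ConfigurationError(f"{name}_range must be increasing")
            if not lo < mean < hi:
                raise ConfigurationError(
                    f"{name}_mean {mean} lies outside its truncation range ({lo}, {hi})"
                )
            if not getattr(self, f"{name}_sd") > 0:
                raise ConfigurationError(f"{name}_sd must be positive")
        if not 0 <= self.enzymatic_fraction <= 1:
            raise ConfigurationError("enzymatic_fraction must be in [0, 1]")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ConfigurationError("sex_probs must sum to 1")

    def latent_corr(self) -> np.ndarray:
        """4x4 latent correlation for (weight, pma, scr, birth_weight)."""
        r = np.eye(4)
        r[:3, :3] = np.asarray(self.copula_corr, dtype=float)
        r[3, 0] = r[0, 3] = self.bw_corr_weight
        r[3, 1] = r[1, 3] = self.bw_corr_pma
        r[3, 2] = r[2, 3] = self.bw_corr_scr
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            raise ConfigurationError("copula correlation matrix is not positive-definite")
        return r


def _matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the target moments."""

    def residual(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, [mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise ConfigurationError(
            f"could not match truncated-normal moments for mean={mean}, sd={sd}, "
            f"range=({lo}, {hi})"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def sample_covariates(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Sample a covariate table (one row per subject) from the cohort spec.

    Returns a DataFrame with columns ``subject_id, weight, pma, pna, ga,
    scr, scr_measured, scr_assay, birth_weight, elbw, sex``.  ``scr`` is on
    the modelling (Jaffe) scale; the raw measurement and assay flag are kept
    so that the assay conversion can be exercised/validated downstream.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    cols = [
        "subject_id", "weight", "pma", "pna", "ga", "scr",
        "scr_measured", "scr_assay", "birth_weight", "elbw", "sex",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)

    corr = spec.latent_corr()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 4)) @ chol.T
    u = norm.cdf(z)

    marginals = {}
    for j, name in enumerate(("weight", "pma", "scr", "birth_weight")):
        mean = getattr(spec, f"{name}_mean")
        sd = getattr(spec, f"{name}_sd")
        lo, hi = getattr(spec, f"{name}_range")
        mu, sigma = _matched_truncnorm_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        marginals[name] = truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sigma)

    pna = rng.integers(spec.pna_range[0], spec.pna_range[1] + 1, size=n).astype(float)
    ga = marginals["pma"] - pna / 7.0
    sex = rng.choice(["male", "female", "missing"], size=n, p=spec.sex_probs)
    assay = np.where(rng.random(n) < spec.enzymatic_fraction, "enzymatic", "jaffe")

    scr_jaffe = marginals["scr"]
    # Raw measurement on the assay's own scale; converting it back with the
    # documented calibration recovers the modelling-scale value exactly.
    scr_measured = np.where(assay == "enzymatic", (scr_jaffe - 0.122) * 1.05, scr_jaffe)

    df = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "weight": marginals["weight"],
            "pma": marginals["pma"],
            "pna": pna,
            "ga": ga,
            "scr": scr_measured,
            "scr_measured": scr_measured,
            "scr_assay": assay,
            "birth_weight": marginals["birth_weight"],
            "elbw": marginals["birth_weight"] < 1.0,
            "sex": sex,
        }
    )
    return standardize_scr(df)


def standardize_scr(cohort: pd.DataFrame) -> pd.DataFrame:
    """Convert enzymatic-assay creatinine rows to the Jaffe scale, exactly once.

    The returned frame carries ``attrs["scr_standardized"] = True``; applying
    the conversion to an already-standardized frame raises, guarding against
    accidental double conversion.
    """
    if cohort.attrs.get("scr_standardized", False):
        raise ValueError("creatinine is already on the Jaffe scale; refusing to convert twice")
    out = cohort.copy()
    enz = out["scr_assay"] == "enzymatic"
    out.loc[enz, "scr"] = convert_scr_enzymatic_to_jaffe(out.loc[enz, "scr"].to_numpy())
    out.attrs["scr_standardized"] = True
    return out


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> list[CovariateProfile]:
    """Sample the cohort as a list of :class:`CovariateProfile`."""
    df = sample_covariates(spec, seed=seed)
    return [
        CovariateProfile(
            subject_id=int(r.subject_id),
            weight=float(r.weight),
            pma=float(r.pma),
            pna=float(r.pna),
            scr=float(r.scr),
            ga=float(r.ga),
            sex=str(r.sex),
            elbw=bool(r.elbw),
            birth_weight=float(r.birth_weight),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# reference dosing regimens
# ---------------------------------------------------------------------------

def reference_regimen(
    cov: CovariateProfile,
    reference: str = "neofax",
    dose_per_kg: float | None = None,
    infusion_duration: float = 1.0,
) -> Regimen:
    """Initial vancomycin regimen per a tertiary neonatal dosing reference.

    ``"neofax"`` and ``"lexicomp_age"`` select the interval from PMA/PNA
    bands; ``"lexicomp_renal"`` selects dose and interval from GA/creatinine
    bands (gaps between the printed creatinine bands are closed at band
    midpoints).  Where the reference prints a dose range (10-15 mg/kg) the
    configured point dose (default 15) is used.
    """
    dose = 15.0 if dose_per_kg is None else dose_per_kg
    pma, pna = cov.pma, cov.pna
    if reference == "neofax":
        if pma < 30:
            interval = 18.0 if pna <= 14 else 12.0
        elif pma < 37:
            interval = 12.0 if pna <= 14 else 8.0
        elif pma < 45:
            interval = 12.0 if pna <= 7 else 8.0
        else:
            interval = 6.0
    elif reference == "lexicomp_age":
        if pma < 30:
            interval = 18.0 if pna <= 21 else 12.0
        elif pma < 37:
            interval = 12.0 if pna <= 14 else 8.0
        elif pma <= 45:
            interval = 12.0 if pna <= 7 else 8.0
        else:
            raise DomainError(f"PMA {pma} outside the lexicomp age-directed table")
    elif reference == "lexicomp_renal":
        if cov.ga is None:
            raise DomainError("lexicomp_renal dosing requires gestational age")
        scr = cov.scr
        if cov.ga <= 28:
            bands = [(0.5, 15.0, 12.0), (0.75, 20.0, 24.0), (1.05, 15.0, 24.0),
                     (1.45, 10.0, 24.0), (math.inf, 15.0, 48.0)]
        else:
            bands = [(0.7, 15.0, 12.0), (0.95, 20.0, 24.0), (1.25, 15.0, 24.0),
                     (1.65, 10.0, 24.0), (math.inf, 15.0, 48.0)]
        for upper, band_dose, band_interval in bands:
            if scr < upper:
                dose, interval = band_dose, band_interval
                break
    else:
        raise ConfigurationError(f"unknown dosing reference {reference!r}")
    return Regimen(dose_per_kg=dose, interval=interval, infusion_duration=infusion_duration)


# ---------------------------------------------------------------------------
# sparse-sampling simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingDesign:
    """Sparse steady-state sampling plan.

    Every subject contributes one steady-state trough (drawn 30 min before a
    dose); a fraction contributes a second trough one interval later, and a
    fraction contributes a peak 1 h after the end of an infusion.  Steady
    state is declared after the later of ``min_dosing_time`` hours of dosing
    or ``halflife_multiple`` individual half-lives.
    """

    second_trough_fraction: float = 0.32
    peak_fraction: float = 0.10
    trough_lead: float = 0.5
    peak_delay: float = 1.0
    min_dosing_time: float = 72.0
    halflife_multiple: float = 5.0
    lloq: float | None = None

    def __post_init__(self) -> None:
        for name in ("second_trough_fraction", "peak_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.trough_lead <= 0 or self.peak_delay < 0:
            raise ConfigurationError("invalid sampling offsets")


def simulate_observations(
    cohort: Sequence[CovariateProfile] | pd.DataFrame,
    model: PopulationModel,
    design: SamplingDesign | None = None,
    seed: int = 0,
    regimens: Sequence[Regimen] | None = None,
    reference: str = "neofax",
) -> EventTable:
    """Simulate a sparse monitoring dataset under the population model.

    Individual parameters are drawn lognormally, concentrations computed by
    dose superposition at the scheduled sampling times, and residual error
    applied according to the model's error specification (negative simulated
    measurements, possible in the tail of the proportional-error model, are
    redrawn).  The returned :class:`EventTable` carries a ``truth`` frame
    with each subject's simulated etas and individual parameters.
    """
    design = design or SamplingDesign()
    if isinstance(cohort, pd.DataFrame):
        cohort = sample_cohort_from_frame(cohort)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for cov in cohort:
        regimen = (
            regimens[len(truth_rows)]
            if regimens is not None
            else reference_regimen(cov, reference=reference)
        )
        tau = regimen.interval
        tinf = regimen.infusion_duration
        dose_mg = float(regimen.dose_mg(cov.weight))
        typ_cl = float(model.typical_cl(cov.weight, cov.scr, cov.pma))
        typ_v = float(model.typical_v(cov.weight))
        eta_cl = rng.normal(0.0, model.omega_cl) if model.omega_cl > 0 else 0.0
        eta_v = rng.normal(0.0, model.omega_v) if model.omega_v > 0 else 0.0
        cl_i = typ_cl * math.exp(eta_cl)
        v_i = typ_v * math.exp(eta_v)
        # Steady state is declared from the *typical* (covariate-predicted)
        # half-life, as a clinician scheduling a trough would: the sampling
        # schedule must not depend on the subject's realised random effects,
        # or the design itself becomes informative about eta and biases any
        # likelihood that treats sampling times as fixed.
        t_half_typ = math.log(2.0) / (typ_cl / typ_v)
        t_ready = max(design.min_dosing_time, design.halflife_multiple * t_half_typ)
        k = int(math.ceil(t_ready / tau))  # trough precedes the k-th dose

        obs_times = [k * tau - design.trough_lead]
        kinds = ["trough"]
        last_dose_index = k
        if rng.random() < design.second_trough_fraction:
            obs_times.append((k + 1) * tau - design.trough_lead)
            kinds.append("trough")
            last_dose_index = k + 1
        if rng.random() < design.peak_fraction:
            obs_times.append(k * tau + tinf + design.peak_delay)
            kinds.append("peak")

        dose_times = np.arange(last_dose_index + 1) * tau
        conc = infusion_concentration(obs_times, dose_times, dose_mg, cl_i, v_i, tinf)
        sd = np.asarray(model.residual_sd(conc), dtype=float)
        dv = np.empty_like(conc)
        for j, (f, s) in enumerate(zip(conc, sd)):
            val = f + s * rng.standard_normal()
            while val <= 0:  # redraw the rare sub-zero tail
                val = f + s * rng.standard_normal()
            dv[j] = val

        common = {
            "ID": cov.subject_id, "WT": cov.weight, "PMA": cov.pma,
            "PNA": cov.pna, "GA": cov.ga if cov.ga is not None else np.nan,
            "SCR": cov.scr, "SEX": cov.sex,
        }
        for t in dose_times:
            rows.append({**common, "TIME": float(t), "EVID": 1, "AMT": dose_mg,
                         "RATE": dose_mg / tinf, "DV": np.nan})
        for t, v_obs in zip(obs_times, dv):
            val = float(v_obs)
            if design.lloq is not None and val < design.lloq:
                val = design.lloq
            rows.append({**common, "TIME": float(t), "EVID": 0, "AMT": np.nan,
                         "RATE": np.nan, "DV": val})
        truth_rows.append({
            "ID": cov.subject_id, "ETA_CL": eta_cl, "ETA_V": eta_v,
            "CL": cl_i, "V": v_i, "TYP_CL": typ_cl, "TYP_V": typ_v,
        })

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return EventTable(df, truth=pd.DataFrame(truth_rows))


def sample_cohort_from_frame(df: pd.DataFrame) -> list[CovariateProfile]:
    """Convert a covariate DataFrame (as from :func:`sample_covariates`)."""
    return [
        CovariateProfile(
            subject_id=r.subject_id,
            weight=float(r.weight),
            pma=float(r.pma),
            pna=float(r.pna),
            scr=float(r.scr),
            ga=float(r.ga) if hasattr(r, "ga") else None,
            sex=str(r.sex) if hasattr(r, "sex") else "missing",
            elbw=bool(r.elbw) if hasattr(r, "elbw") else None,
            birth_weight=float(r.birth_weight) if hasattr(r, "birth_weight") else None,
        )
        for r in df.itertuples()
    ]


def split_dataset(
    table: EventTable, fraction: float = 0.7, seed: int = 0
) -> tuple[EventTable, EventTable]:
    """Random by-subject train/validation split.

    The split is always by subject (never by observation); sizes follow
    ``round(fraction * n_subjects)``.  Deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must lie strictly between 0 and 1")
    ids = table.subject_ids
    if len(ids) < 2:
        raise DataError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = [ids[i] for i in perm[:n_train]]
    valid_ids = [ids[i] for i in perm[n_train:]]
    return table.subset(train_ids), table.subset(valid_ids)
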