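"""Model evaluation: goodness-of-fit residuals, VPC and NPDE.

The Visual Predictive Check (VPC) compares observed concentration
percentiles per sampling occasion with 90% confidence bands of the same
percentiles across simulated replicate datasets.  The Normalized
Prediction Distribution Errors (NPDE) decorrelate each subject's observed
vector with the simulation-based within-subject covariance and transform
empirical ranks to normal scores; under a correct model they are N(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from ._design import Design, build_design, predicted_concentration
from .errors import ConfigurationError
from .estimation import FitResult
from .events import EventTable
from .model import PopulationModel

__all__ = ["DiagnosticsSummary", "vpc", "npde", "gof_residuals", "simulate_replicates"]


@dataclass
class DiagnosticsSummary:
    """Container for diagnostic outputs (fields filled per operation)."""

    npde_values: np.ndarray | None = None
    npde_mean: float | None = None
    npde_sd: float | None = None
    normality_p: float | None = None
    vpc_bands: pd.DataFrame | None = None
    vpc_coverage: float | None = None
    pwres: np.ndarray | None = None
    iwres: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def simulate_replicates(
    design: Design,
    model: PopulationModel,
    n_sim: int,
    rng: np.random.Generator,
    chunk: int = 200,
) -> np.ndarray:
    """Simulate ``n_sim`` replicate observation vectors under the design.

    Fresh random effects per subject and residual errors per observation;
    the rare negative proportional-error draws are redrawn, matching the
    data generator.  Returns an ``(n_sim, n_obs)`` array.
    """
    typ_cl = np.asarray(model.typical_cl(design.weight, design.scr, design.pma))
    typ_v = np.asarray(model.typical_v(design.weight))
    n_obs = len(design.y)
    out = np.empty((n_sim, n_obs))
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        eta_cl = rng.normal(0.0, model.omega_cl, size=(m, design.n_subjects))
        eta_v = rng.normal(0.0, model.omega_v, size=(m, design.n_subjects))
        f = predicted_concentration(design, typ_cl * np.exp(eta_cl), typ_v * np.exp(eta_v))
        sd = model.residual_sd(f)
        y = f + sd * rng.standard_normal(f.shape)
        bad = y <= 0
        while bad.any():
            y[bad] = (f + sd * rng.standard_normal(f.shape))[bad]
            bad = y <= 0
        out[done:done + m] = y
        done += m
    return out


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------

def _bin_labels(design: Design, min_bin: int, summary: DiagnosticsSummary) -> np.ndarray:
    """Occasion bins (kind x nominal interval), merging bins below min_bin."""
    raw = np.array(
        [f"{k}-q{t:g}" if np.isfinite(t) else f"{k}" for k, t in
         zip(design.obs_kind, design.tau)],
        dtype=object,
    )
    labels, counts = np.unique(raw, return_counts=True)
    order = list(labels[np.argsort(labels)])
    merged = raw.copy()
    small = [lab for lab, c in zip(labels, counts) if c < min_bin]
    for lab in small:
        idx = order.index(lab)
        neighbor = order[idx - 1] if idx > 0 else (order[idx + 1] if len(order) > 1 else lab)
        if neighbor == lab:
            continue
        msg = f"VPC bin '{lab}' has fewer than {min_bin} observations; merged into '{neighbor}'"
        warnings.warn(msg)
        summary.warnings.append(msg)
        merged[merged == lab] = neighbor
        order.remove(lab)
    return merged


def vpc(
    data: EventTable,
    model: PopulationModel,
    n_sim: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    ci: float = 90.0,
    min_bin: int = 5,
) -> DiagnosticsSummary:
    """Visual predictive check against ``n_sim`` simulated replicate datasets.

    Observations are binned by nominal sampling occasion (trough/peak x
    dosing interval); per bin the observed percentiles are compared with the
    ``ci``% interval of the same percentile across replicates.
    ``vpc_coverage`` is the fraction of observed percentile points inside
    their band.
    """
    if n_sim < 100:
        raise ConfigurationError("vpc requires n_sim >= 100")
    summary = DiagnosticsSummary()
    design = build_design(data)
    rng = np.random.default_rng(seed)
    sims = simulate_replicates(design, model, n_sim, rng)
    bins = _bin_labels(design, min_bin, summary)

    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows = []
    for lab in np.unique(bins):
        idx = np.where(bins == lab)[0]
        obs_p = np.percentile(design.y[idx], percentiles)
        sim_p = np.percentile(sims[:, idx], percentiles, axis=1)  # (3, n_sim)
        lo = np.percentile(sim_p, lo_q, axis=1)
        hi = np.percentile(sim_p, hi_q, axis=1)
        med = np.median(sim_p, axis=1)
        for p, o, l, h, m in zip(percentiles, obs_p, lo, hi, med):
            rows.append({
                "bin": lab, "percentile": p, "n_obs": len(idx),
                "observed": o, "sim_lo": l, "sim_hi": h, "sim_median": m,
                "inside": bool(l <= o <= h),
            })
    bands = pd.DataFrame(rows)
    summary.vpc_bands = bands
    summary.vpc_coverage = float(bands["inside"].mean())
    return summary


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------

def npde(
    data: EventTable,
    model: PopulationModel,
    n_sim: int = 1000,
    seed: int = 0,
) -> DiagnosticsSummary:
    """Normalized prediction distribution errors for every observation.

    Per subject, the observed vector and each simulated replicate are
    decorrelated with the Cholesky factor of the simulation covariance;
    empirical ranks (ties broken by seeded uniform jitter) are mapped
    through the standard-normal quantile function.  Reports mean, SD and a
    Shapiro-Wilk normality p-value.
    """
    if n_sim < 500:
        raise ConfigurationError("npde requires n_sim >= 500")
    summary = DiagnosticsSummary()
    design = build_design(data)
    rng = np.random.default_rng(seed)
    sims = simulate_replicates(design, model, n_sim, rng)

    values = np.empty(len(design.y))
    for i in range(design.n_subjects):
        idx = np.where(design.subj_of_obs == i)[0]
        y = design.y[idx]
        ysim = sims[:, idx]  # (n_sim, n_i)
        mean = ysim.mean(axis=0)
        if len(idx) == 1:
            yd = (y - mean)
            sd = ysim.std(axis=0, ddof=1)
            yd = yd / np.maximum(sd, 1e-12)
            sd_sims = (ysim - mean) / np.maximum(sd, 1e-12)
        else:
            cov = np.cov(ysim.T)
            ridge = 1e-10 * np.trace(cov) / len(idx)
            for _ in range(12):
                try:
                    chol = np.linalg.cholesky(cov + ridge * np.eye(len(idx)))
                    break
                except np.linalg.LinAlgError:
                    ridge = max(ridge, 1e-12) * 10.0
            else:  # pragma: no cover - pathological
                raise np.linalg.LinAlgError("simulated covariance not factorisable")
            if ridge > 1e-8 * np.trace(cov) / len(idx):
                msg = f"subject {design.subject_ids[i]}: singular simulated covariance, ridge-regularised"
                warnings.warn(msg)
                summary.warnings.append(msg)
            yd = solve_triangular(chol, y - mean, lower=True)
            sd_sims = solve_triangular(chol, (ysim - mean).T, lower=True).T
        for j, k in enumerate(idx):
            r = int(np.sum(sd_sims[:, j] < yd[j]))
            t = int(np.sum(sd_sims[:, j] == yd[j]))
            u = rng.uniform()
            values[k] = stats.norm.ppf((r + u * (t + 1)) / (n_sim + 1))

    summary.npde_values = values
    summary.npde_mean = float(values.mean())
    summary.npde_sd = float(values.std(ddof=1))
    summary.normality_p = float(stats.shapiro(values).pvalue)
    return summary


# ---------------------------------------------------------------------------
# goodness-of-fit residuals
# ---------------------------------------------------------------------------

def gof_residuals(
    fit: FitResult,
    data: EventTable,
    n_sim: int = 500,
    seed: int = 0,
) -> DiagnosticsSummary:
    """Population- and individual-weighted residuals.

    PWRES uses the typical prediction and a simulation-based SD of the
    marginal observation distribution; IWRES uses each subject's empirical
    Bayes parameters and the residual-error SD.  Residuals at (near) zero
    predictions are flagged and reported as ``nan``.
    """
    summary = DiagnosticsSummary()
    design = build_design(data)
    model = fit.estimates
    rng = np.random.default_rng(seed)

    typ_cl = np.asarray(model.typical_cl(design.weight, design.scr, design.pma))
    typ_v = np.asarray(model.typical_v(design.weight))
    f_pop = predicted_concentration(design, typ_cl, typ_v)
    sims = simulate_replicates(design, model, n_sim, rng)
    sd_pop = sims.std(axis=0, ddof=1)
    summary.pwres = (design.y - f_pop) / np.maximum(sd_pop, 1e-12)

    ebes = fit.ebes.set_index("ID")
    cl_i = ebes.loc[design.subject_ids, "CL"].to_numpy()
    v_i = ebes.loc[design.subject_ids, "V"].to_numpy()
    f_ind = predicted_concentration(design, cl_i, v_i)
    sd_ind = np.asarray(model.residual_sd(f_ind))
    iwres = np.where(sd_ind > 1e-12, (design.y - f_ind) / np.maximum(sd_ind, 1e-12), np.nan)
    n_bad = int(np.sum(~(sd_ind > 1e-12)))
    if n_bad:
        msg = f"{n_bad} observation(s) with zero prediction: IWRES undefined"
        warnings.warn(msg)
        summary.warnings.append(msg)
    summary.iwres = iwres
    return summary
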