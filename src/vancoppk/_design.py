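"""Internal vectorised data structures for likelihood work.

Flattens an :class:`~vancoppk.events.EventTable` into padded per-observation
dose-geometry arrays so that predicted concentrations for arbitrary
(clearance, volume) arrays — including whole stacks of simulation
replicates — are a handful of numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .events import EventTable

__all__ = ["Design", "build_design", "predicted_concentration"]


@dataclass
class Design:
    y: np.ndarray            # (n_obs,) observed concentrations
    subj_of_obs: np.ndarray  # (n_obs,) subject index of each observation
    n_subjects: int
    subject_ids: list
    weight: np.ndarray       # (n_subj,)
    pma: np.ndarray
    scr: np.ndarray
    dt: np.ndarray           # (n_obs, D) obs time minus dose start (pad < 0)
    rate: np.ndarray         # (n_obs, D) infusion rate mg/h (pad 0)
    tinf: np.ndarray         # (n_obs, D) infusion duration h (pad 1)
    obs_kind: np.ndarray     # (n_obs,) "trough"/"peak"/"other"
    tau: np.ndarray          # (n_obs,) nominal dosing interval of the subject
    obs_per_subject: np.ndarray  # (n_subj,)


def build_design(table: EventTable, allow_no_obs: bool = False) -> Design:
    df = table.data
    subj_ids = table.subject_ids
    index_of = {sid: i for i, sid in enumerate(subj_ids)}
    n_subj = len(subj_ids)

    weight = np.empty(n_subj)
    pma = np.empty(n_subj)
    scr = np.empty(n_subj)
    obs_rows: list[tuple] = []  # (subj_idx, time, dv)
    dose_lists: list[np.ndarray] = [None] * n_subj  # type: ignore[list-item]

    for sid, sub in df.groupby("ID", sort=False):
        i = index_of[sid]
        first = sub.iloc[0]
        weight[i] = first["WT"]
        pma[i] = first["PMA"]
        scr[i] = first["SCR"]
        doses = sub[sub["EVID"] == 1]
        dose_lists[i] = doses[["TIME", "AMT", "RATE"]].to_numpy(dtype=float)
        obs = sub[sub["EVID"] == 0]
        if len(obs) == 0 and not allow_no_obs:
            raise DataError(f"subject {sid}: no observations")
        for _, r in obs.iterrows():
            obs_rows.append((i, float(r["TIME"]), float(r["DV"])))

    if np.any(~np.isfinite(weight)) or np.any(~np.isfinite(pma)) or np.any(~np.isfinite(scr)):
        raise DataError("WT, PMA and SCR must be present for every subject")

    n_obs = len(obs_rows)
    max_d = max((len(d) for d in dose_lists if d is not None), default=1)
    max_d = max(max_d, 1)
    dt = np.full((n_obs, max_d), -1.0)
    rate = np.zeros((n_obs, max_d))
    tinf = np.ones((n_obs, max_d))
    y = np.empty(n_obs)
    subj_of_obs = np.empty(n_obs, dtype=int)
    kind = np.empty(n_obs, dtype=object)
    tau_arr = np.empty(n_obs)

    for j, (i, t, dv) in enumerate(obs_rows):
        y[j] = dv
        subj_of_obs[j] = i
        doses = dose_lists[i]
        nd = len(doses)
        if nd:
            dt[j, :nd] = t - doses[:, 0]
            rate[j, :nd] = doses[:, 2]
            tinf[j, :nd] = doses[:, 1] / doses[:, 2]
        # nominal interval: spacing of the subject's scheduled doses
        tau = float(np.median(np.diff(doses[:, 0]))) if nd > 1 else np.nan
        tau_arr[j] = tau
        kind[j] = _classify(t, doses, tau)

    obs_per_subject = np.bincount(subj_of_obs, minlength=n_subj)
    return Design(
        y=y, subj_of_obs=subj_of_obs, n_subjects=n_subj, subject_ids=subj_ids,
        weight=weight, pma=pma, scr=scr, dt=dt, rate=rate, tinf=tinf,
        obs_kind=np.asarray(kind, dtype=object), tau=tau_arr,
        obs_per_subject=obs_per_subject,
    )


def _classify(t: float, doses: np.ndarray, tau: float) -> str:
    """Label an observation by its nominal monitoring occasion."""
    if len(doses) == 0 or not np.isfinite(tau):
        return "other"
    prior = doses[doses[:, 0] <= t]
    if len(prior) == 0:
        return "other"
    last = prior[-1]
    t_inf_end = last[0] + last[1] / last[2]
    since_inf_end = t - t_inf_end
    next_doses = doses[doses[:, 0] > t]
    until_next = (next_doses[0, 0] - t) if len(next_doses) else (last[0] + tau - t)
    if 0.0 < until_next <= 1.0:
        return "trough"
    if 0.0 <= since_inf_end <= 2.0:
        return "peak"
    return "other"


def predicted_concentration(design: Design, cl, v) -> np.ndarray:
    """Model-predicted concentrations at the design's observation times.

    ``cl`` and ``v`` have shape ``(..., n_subjects)``; the result has shape
    ``(..., n_obs)``.  Leading axes (e.g. simulation replicates) broadcast.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    cl_o = cl[..., design.subj_of_obs]
    ke_o = cl_o / v[..., design.subj_of_obs]
    te = np.clip(design.dt, 0.0, design.tinf)
    td = np.clip(design.dt - design.tinf, 0.0, None)
    conc = (
        (design.rate / cl_o[..., None])
        * (-np.expm1(-ke_o[..., None] * te))
        * np.exp(-ke_o[..., None] * td)
    )
    return conc.sum(axis=-1)
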