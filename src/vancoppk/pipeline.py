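"""End-to-end orchestration: generate -> fit -> diagnose -> simulate -> recommend.

``run_pipeline`` executes the stages in order, writes every artifact as a
plain-text file (event CSVs, fit JSON, diagnostic CSVs, PTA CSV,
recommendation JSON) and finishes with a manifest recording seeds, the
package version and SHA-256 checksums of the outputs.  Re-running the same
configuration reproduces byte-identical numeric outputs.  A stage failure
is recorded in the manifest and downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import sample_cohort, sample_covariates, simulate_observations, split_dataset
from .config import RunConfig
from .diagnostics import npde, vpc
from .dosing import pta_for_grid, recommend_dose
from .estimation import ModelStructure, compute_rse, fit_population
from .events import EventTable

__all__ = ["run_pipeline"]

log = logging.getLogger("vancoppk")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis described by ``config``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "name": config.name,
        "version": __version__,
        "config": config.model_dump(mode="json"),
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, status: str, **extra) -> None:
        manifest["stages"][stage] = {"status": status, **extra}
        log.info("stage %s: %s", stage, status)

    def write_df(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, na_rep=".")
        artifacts[name] = path

    model = config.model.build()
    fitted = None
    train = valid = None

    # -- cohort + data simulation --------------------------------------
    try:
        spec = config.cohort.build()
        cov = sample_covariates(spec)
        write_df("cohort.csv", cov)
        cohort = sample_cohort(spec)
        table = simulate_observations(
            cohort, model, design=config.sampling.build(),
            seed=config.sampling.seed, reference=config.sampling.reference,
        )
        table.to_csv(outdir / "events.csv")
        artifacts["events.csv"] = outdir / "events.csv"
        write_df("truth.csv", table.truth)
        train, valid = split_dataset(table, config.split_fraction, config.split_seed)
        train.to_csv(outdir / "train.csv")
        valid.to_csv(outdir / "validation.csv")
        artifacts["train.csv"] = outdir / "train.csv"
        artifacts["validation.csv"] = outdir / "validation.csv"
        record("generate", "ok", n_subjects=table.n_subjects,
               n_observations=table.n_observations,
               n_train=train.n_subjects, n_validation=valid.n_subjects)
    except Exception as exc:  # noqa: BLE001 - manifest records the failure
        record("generate", "failed", error=str(exc))
        return _finalise(manifest, artifacts, outdir)

    # -- estimation ----------------------------------------------------
    try:
        est = config.estimation
        structure = ModelStructure(
            include_scr=est.include_scr,
            include_maturation=est.include_maturation,
            error_model=est.error_model,
        )
        fitted = fit_population(train, structure, seed=est.seed, maxfev=est.maxfev)
        if est.rse_method != "none":
            compute_rse(fitted, method=est.rse_method, n_boot=est.n_boot, seed=est.seed)
        fitted.to_json(outdir / "fit.json")
        artifacts["fit.json"] = outdir / "fit.json"
        write_df("ebes.csv", fitted.ebes)
        record("fit", "ok", ofv=fitted.ofv, converged=fitted.converged)
    except Exception as exc:  # noqa: BLE001
        record("fit", "failed", error=str(exc))
        return _finalise(manifest, artifacts, outdir)

    eval_model = fitted.estimates if config.dose_sim.use_model == "fitted" else model

    # -- diagnostics on the held-out split -----------------------------
    try:
        diag = config.diagnostics
        vpc_summary = vpc(valid, eval_model, n_sim=diag.n_sim_vpc, seed=diag.seed)
        write_df("vpc_bands.csv", vpc_summary.vpc_bands)
        npde_summary = npde(valid, eval_model, n_sim=diag.n_sim_npde, seed=diag.seed)
        obs = valid.observations()
        write_df("npde.csv", pd.DataFrame({
            "ID": obs["ID"].to_numpy(),
            "TIME": obs["TIME"].to_numpy(),
            "DV": obs["DV"].to_numpy(),
            "NPDE": npde_summary.npde_values,
        }))
        record("diagnose", "ok", vpc_coverage=vpc_summary.vpc_coverage,
               npde_mean=npde_summary.npde_mean, npde_sd=npde_summary.npde_sd,
               npde_normality_p=npde_summary.normality_p)
    except Exception as exc:  # noqa: BLE001
        record("diagnose", "failed", error=str(exc))
        return _finalise(manifest, artifacts, outdir)

    # -- dosing simulation + recommendation ----------------------------
    try:
        ds = config.dose_sim
        pta = pta_for_grid(
            cov, ds.grid(), eval_model, replicate=ds.replicate,
            seed=ds.seed, metric=ds.metric,
        )
        write_df("pta.csv", pta)
        rec = recommend_dose(pta, config.policy.build())
        rec_path = outdir / "recommendations.json"
        rec_path.write_text(json.dumps(rec.to_dict(orient="records"), indent=2,
                                       default=_json_default))
        artifacts["recommendations.json"] = rec_path
        record("dose_sim", "ok", n_rows=len(pta))
    except Exception as exc:  # noqa: BLE001
        record("dose_sim", "failed", error=str(exc))
        return _finalise(manifest, artifacts, outdir)

    return _finalise(manifest, artifacts, outdir)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not serialisable: {type(obj)}")


def _finalise(manifest: dict, artifacts: dict, outdir: Path) -> dict:
    for name, path in artifacts.items():
        manifest["artifacts"][name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=_json_default))
    return manifest
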