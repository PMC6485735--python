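"""Pipeline orchestration: simulate -> process -> psych -> modelfit -> report.

Each stage reads the previous stage's artifacts from the output directory
and writes tidy delimited tables (plus a JSON log entry).  The whole
pipeline is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import processing as proc
from . import psychophysics as psy
from .io import RunConfig, read_manifest, read_trace_file, write_manifest, write_trace_file
from .models import MODEL_KINDS, SineLiftParams, fit_duration, fit_weight, compare_models
from .synthetic import (
    GRAVITY,
    make_design_exp1,
    simulate_experiment1,
)

STAGES = ("simulate", "process", "psych", "modelfit", "report")

__all__ = ["STAGES", "run_pipeline"]


def _weight_n(mass_g: float) -> float:
    return mass_g / 1000.0 * GRAVITY


def _log(outdir: Path, stage: str, payload: dict[str, Any]) -> None:
    log_path = outdir / "pipeline_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    log[stage] = payload
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))


# ---------------------------------------------------------------- simulate


def stage_simulate(cfg: RunConfig) -> dict[str, Any]:
    outdir = Path(cfg.outdir)
    traces_dir = outdir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)

    # experiment-1: lift traces + magnitude-estimation ratings
    all_records, rating_frames = [], []
    for p in range(cfg.participants_exp1):
        participant = f"p{p + 1:02d}"
        pseed = int(master.integers(2**31))
        design = make_design_exp1(
            pseed,
            participant=participant,
            masses=cfg.masses_g,
            delays=cfg.delays_ms,
            n_no_delay=cfg.n_no_delay,
            n_delay=cfg.n_delay,
        )
        prng = np.random.default_rng(pseed)
        # participant-specific lift tempo and rating scale
        lift_cfg = cfg.lift_config(
            true_duration_d=float(prng.uniform(0.35, 0.45)), seed=pseed
        )
        obs = cfg.observer_config(
            rating_scale=float(prng.uniform(0.5, 2.0)), seed=pseed
        )
        records, ratings = simulate_experiment1(design, lift_cfg, obs, seed=pseed)
        all_records.extend(records)
        rating_frames.append(ratings)

    manifest_records = []
    for rec in all_records:
        rel = f"traces/{rec.trial_id}.csv"
        write_trace_file(rec.trace, outdir / rel)
        manifest_records.append((rec, rel))
    write_manifest(outdir / "manifest.json", "exp1", cfg.seed, manifest_records)
    ratings_df = pd.concat(rating_frames, ignore_index=True)
    ratings_df.to_csv(outdir / "ratings.csv", index=False, float_format="%.9g")

    # experiment-2: interleaved staircase sessions (choices only)
    rows = []
    for p in range(cfg.participants_exp2):
        participant = f"s{p + 1:02d}"
        pseed = int(master.integers(2**31))
        obs = cfg.observer_config(seed=pseed)
        srng = np.random.default_rng(pseed)
        for placement in ("standard", "test"):
            session = psy.StaircaseSession(
                delay_placement=placement, delay_level=cfg.exp2_delay_ms
            )
            psy.run_session(obs, session, srng)
            for i, (chain, mass, response) in enumerate(session.history):
                rows.append(
                    {
                        "participant": participant,
                        "delay_placement": placement,
                        "delay_ms": cfg.exp2_delay_ms,
                        "comparison": i,
                        "chain": chain,
                        "test_mass_g": mass,
                        "response": response,
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "staircase_sessions.csv", index=False)

    info = {
        "n_trials_exp1": len(all_records),
        "n_participants_exp1": cfg.participants_exp1,
        "n_sessions_exp2": 2 * cfg.participants_exp2,
        "seed": cfg.seed,
    }
    _log(outdir, "simulate", info)
    return info


# ----------------------------------------------------------------- process


def stage_process(cfg: RunConfig) -> dict[str, Any]:
    outdir = Path(cfg.outdir)
    manifest = read_manifest(outdir / "manifest.json")

    param_rows, kin_rows, screen_items = [], [], []
    processed: dict[str, tuple[proc.GripLoadSeries, proc.LiftEvents, dict]] = {}
    for entry in manifest["trials"]:
        trial_id = entry["trial_id"]
        meta = {
            "participant": entry["participant"],
            "mass_g": entry["mass_g"],
            "delay_ms": entry["delay_ms"],
        }
        weight = _weight_n(entry["mass_g"])
        trace = read_trace_file(outdir / entry["file"], **{})
        try:
            filtered = proc.preprocess(
                trace, cutoff=cfg.filter_cutoff_hz, order=cfg.filter_order
            )
            gls = proc.grip_load(filtered)
            events = proc.detect_events(gls, weight, threshold=cfg.onset_threshold_n)
        except proc.TrialError as err:
            screen_items.append(
                proc.ScreenInput(
                    trial_id=trial_id,
                    gls=None,
                    events=None,
                    cube_weight=weight,
                    failure=err.reason,
                )
            )
            continue

        start_offset = None
        if trace.thumb_pos is not None and trace.index_pos is not None:
            mean_start = 0.5 * (trace.thumb_pos[0] + trace.index_pos[0])
            start_offset = float(np.linalg.norm(mean_start))
        screen_items.append(
            proc.ScreenInput(
                trial_id=trial_id,
                gls=gls,
                events=events,
                cube_weight=weight,
                start_offset_mm=start_offset,
            )
        )
        fp = proc.force_parameters(gls, events)
        param_rows.append(
            {
                "trial_id": trial_id,
                **meta,
                "lf_onset_s": events.lf_onset,
                "gf_onset_s": events.gf_onset,
                "liftoff_s": events.liftoff,
                "lfr_max_n_per_s": fp.lfr_max,
                "gfr_max_n_per_s": fp.gfr_max,
                "lpd_s": fp.lpd,
                "gf_at_lo_n": fp.gf_at_lo,
            }
        )
        processed[trial_id] = (gls, events, meta)
        if trace.thumb_pos is not None:
            try:
                kin = proc.kinematics(trace, events)
                kin_rows.append(
                    {
                        "trial_id": trial_id,
                        **meta,
                        "peak_velocity_mm_per_s": kin.peak_velocity,
                        "path_length_mm": kin.path_length,
                        "curvature_mm": kin.curvature,
                        "contact_pos_thumb_mm": kin.contact_position_thumb,
                        "contact_pos_index_mm": kin.contact_position_index,
                    }
                )
            except proc.TrialError:
                pass

    screen_df = proc.screen_trials(
        screen_items,
        drop_fraction=cfg.drop_fraction,
        start_tolerance_mm=cfg.start_tolerance_mm,
    )
    screen_df.to_csv(outdir / "exclusions.csv", index=False)
    params_df = pd.DataFrame(param_rows)
    params_df.to_csv(outdir / "trial_parameters.csv", index=False, float_format="%.9g")

    kept = set(screen_df.loc[screen_df["keep"], "trial_id"])
    kin_ok = set(screen_df.loc[screen_df["kinematics_ok"], "trial_id"])
    kin_df = pd.DataFrame(kin_rows)
    if not kin_df.empty:
        kin_df = kin_df[kin_df["trial_id"].isin(kin_ok)]
    kin_df.to_csv(outdir / "kinematics.csv", index=False, float_format="%.9g")

    # per participant x condition averaged curves + binned areas
    curve_rows, bin_rows = [], []
    groups: dict[tuple, list[str]] = {}
    for trial_id, (_, _, meta) in processed.items():
        if trial_id not in kept:
            continue
        key = (meta["participant"], meta["mass_g"], meta["delay_ms"])
        groups.setdefault(key, []).append(trial_id)
    for (participant, mass, delay), ids in sorted(groups.items()):
        series = [processed[t][0] for t in ids]
        events = [processed[t][1] for t in ids]
        avg = proc.average_curves(series, events)
        for t, lf, gf in zip(avg.time, avg.lf, avg.gf):
            curve_rows.append(
                {
                    "participant": participant,
                    "mass_g": mass,
                    "delay_ms": delay,
                    "time_s": t,
                    "lf_n": lf,
                    "gf_n": gf,
                    "n_trials": avg.n_trials,
                }
            )
        dt = float(avg.time[1] - avg.time[0])
        avg_gls = proc.GripLoadSeries(
            time=avg.time,
            gf=avg.gf,
            lf=avg.lf,
            gfr=np.gradient(avg.gf, dt),
            lfr=np.gradient(avg.lf, dt),
        )
        try:
            ev = proc.detect_events(
                avg_gls, _weight_n(mass), threshold=cfg.onset_threshold_n
            )
            bins = proc.binned_areas(avg_gls, ev)
            for k in range(bins.lf.size):
                bin_rows.append(
                    {
                        "participant": participant,
                        "mass_g": mass,
                        "delay_ms": delay,
                        "bin": k,
                        "lf_area_ns": bins.lf[k],
                        "gf_area_ns": bins.gf[k],
                        "lfr_area_n": bins.lfr[k],
                        "gfr_area_n": bins.gfr[k],
                    }
                )
        except (proc.TrialError, ValueError):
            pass
    pd.DataFrame(curve_rows).to_csv(
        outdir / "averaged_curves.csv", index=False, float_format="%.9g"
    )
    pd.DataFrame(bin_rows).to_csv(
        outdir / "binned_areas.csv", index=False, float_format="%.9g"
    )

    reasons = screen_df["reason"].value_counts().to_dict()
    info = {
        "n_trials": len(manifest["trials"]),
        "n_kept": int(screen_df["keep"].sum()),
        "exclusions": {str(k): int(v) for k, v in reasons.items() if k != "none"},
    }
    _log(outdir, "process", info)
    return info


# -------------------------------------------------------------------- psych


def stage_psych(cfg: RunConfig) -> dict[str, Any]:
    outdir = Path(cfg.outdir)
    ratings = pd.read_csv(outdir / "ratings.csv")
    summary = psy.zscore_ratings(ratings)
    summary.table.to_csv(outdir / "zscores.csv", index=False, float_format="%.9g")

    sessions = pd.read_csv(outdir / "staircase_sessions.csv")
    fit_rows, bias_rows = [], []
    for participant, pgrp in sessions.groupby("participant"):
        fits = {}
        for placement, sgrp in pgrp.groupby("delay_placement"):
            counts = sgrp.groupby("test_mass_g").agg(
                n_presented=("response", "size"),
                n_test_heavier=(
                    "response",
                    lambda r: int((r == "test_heavier").sum()),
                ),
            )
            data = psy.PsychometricData(
                masses=counts.index.to_numpy(dtype=float),
                n_presented=counts["n_presented"].to_numpy(),
                n_test_heavier=counts["n_test_heavier"].to_numpy(),
                n_lifts=2 * len(sgrp),
            )
            try:
                fit = psy.fit_psychometric(data)
            except psy.PsychometricFitError as err:
                fit_rows.append(
                    {
                        "participant": participant,
                        "delay_placement": placement,
                        "delay_ms": float(sgrp["delay_ms"].iloc[0]),
                        "mu_g": np.nan,
                        "sigma_g": np.nan,
                        "residual_pct": np.nan,
                        "error": str(err),
                    }
                )
                continue
            fits[placement] = fit
            fit_rows.append(
                {
                    "participant": participant,
                    "delay_placement": placement,
                    "delay_ms": float(sgrp["delay_ms"].iloc[0]),
                    "mu_g": fit.mu,
                    "sigma_g": fit.sigma,
                    "residual_pct": fit.residual,
                    "error": "",
                }
            )
        if {"standard", "test"} <= set(fits):
            bias = psy.total_bias(fits["standard"], fits["test"])
            bias_rows.append(
                {
                    "participant": participant,
                    "delay_ms": float(pgrp["delay_ms"].iloc[0]),
                    "mu_standard_delay_g": bias.mu_standard_delay,
                    "mu_test_delay_g": bias.mu_test_delay,
                    "total_bias_pct": bias.total_bias,
                    "clamped": bias.clamped,
                }
            )
    pd.DataFrame(fit_rows).to_csv(
        outdir / "psychometric_fits.csv", index=False, float_format="%.9g"
    )
    bias_df = pd.DataFrame(bias_rows)
    bias_df.to_csv(outdir / "bias_summary.csv", index=False, float_format="%.9g")

    info = {
        "n_participants_rated": int(ratings["participant"].nunique()),
        "n_bias_estimates": len(bias_rows),
        "mean_total_bias_pct": (
            float(bias_df["total_bias_pct"].mean()) if len(bias_rows) else None
        ),
    }
    _log(outdir, "psych", info)
    return info


# ----------------------------------------------------------------- modelfit


def stage_modelfit(cfg: RunConfig) -> dict[str, Any]:
    outdir = Path(cfg.outdir)
    curves = pd.read_csv(outdir / "averaged_curves.csv")
    fit_rows = []
    for (participant, mass), grp in curves.groupby(["participant", "mass_g"]):
        weight = _weight_n(mass)
        base = grp[grp["delay_ms"] == 0.0].sort_values("time_s")
        if base.empty:
            continue
        t = base["time_s"].to_numpy()
        lf = base["lf_n"].to_numpy()
        dt = t[1] - t[0]
        gls = proc.GripLoadSeries(
            time=t, gf=base["gf_n"].to_numpy(), lf=lf,
            gfr=np.gradient(base["gf_n"].to_numpy(), dt), lfr=np.gradient(lf, dt),
        )
        try:
            ev = proc.detect_events(gls, weight, threshold=cfg.onset_threshold_n)
        except proc.TrialError:
            continue
        dur = fit_duration(
            t, lf, weight, gf_onset=0.0, liftoff=ev.liftoff,
            bounds=cfg.duration_bounds,
        )
        fit_rows.append(
            {
                "participant": participant,
                "mass_g": mass,
                "delay_ms": 0.0,
                "kind": "base",
                "d_s": dur.d,
                "w_v": np.nan,
                "rmse_n": dur.rmse,
                "n_samples": dur.n,
                "converged": dur.converged,
            }
        )
        p = SineLiftParams(m=weight, d=dur.d, onset=0.0)
        for delay_ms, dgrp in grp[grp["delay_ms"] > 0].groupby("delay_ms"):
            dgrp = dgrp.sort_values("time_s")
            td = dgrp["time_s"].to_numpy()
            lfd = dgrp["lf_n"].to_numpy()
            dtd = td[1] - td[0]
            gls_d = proc.GripLoadSeries(
                time=td, gf=dgrp["gf_n"].to_numpy(), lf=lfd,
                gfr=np.gradient(dgrp["gf_n"].to_numpy(), dtd),
                lfr=np.gradient(lfd, dtd),
            )
            try:
                ev_d = proc.detect_events(
                    gls_d, weight, threshold=cfg.onset_threshold_n
                )
            except proc.TrialError:
                continue
            for kind in MODEL_KINDS:
                fit = fit_weight(
                    td, lfd, kind, p, delay=delay_ms / 1000.0,
                    gf_onset=0.0, liftoff=ev_d.liftoff, bounds=cfg.weight_bounds,
                )
                fit_rows.append(
                    {
                        "participant": participant,
                        "mass_g": mass,
                        "delay_ms": delay_ms,
                        "kind": kind,
                        "d_s": fit.d,
                        "w_v": fit.w_v,
                        "rmse_n": fit.rmse,
                        "n_samples": fit.n,
                        "converged": fit.converged,
                    }
                )
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(outdir / "model_fits.csv", index=False, float_format="%.9g")

    delay_fits = fits_df[fits_df["kind"].isin(MODEL_KINDS)].rename(
        columns={"rmse_n": "rmse"}
    )
    if not delay_fits.empty:
        per_condition, aggregate = compare_models(delay_fits)
        per_condition.to_csv(
            outdir / "model_comparison.csv", index=False, float_format="%.9g"
        )
        aggregate.to_csv(
            outdir / "model_aggregate.csv", index=False, float_format="%.9g"
        )
        best = aggregate.loc[aggregate["mean_rmse"].idxmin(), "kind"]
    else:
        best = None
    info = {"n_fits": len(fits_df), "best_kind_by_mean_rmse": best}
    _log(outdir, "modelfit", info)
    return info


# ------------------------------------------------------------------- report


def stage_report(cfg: RunConfig) -> dict[str, Any]:
    outdir = Path(cfg.outdir)
    report: dict[str, Any] = {"seed": cfg.seed}

    exclusions = pd.read_csv(outdir / "exclusions.csv")
    report["trials"] = {
        "total": len(exclusions),
        "kept": int(exclusions["keep"].sum()),
        "excluded_by_reason": {
            str(k): int(v)
            for k, v in exclusions.loc[~exclusions["keep"], "reason"]
            .value_counts()
            .items()
        },
    }
    params = pd.read_csv(outdir / "trial_parameters.csv")
    if not params.empty:
        cond = (
            params.groupby(["mass_g", "delay_ms"])[
                ["lfr_max_n_per_s", "gfr_max_n_per_s", "lpd_s", "gf_at_lo_n"]
            ]
            .mean()
            .round(6)
        )
        report["force_parameters_by_condition"] = {
            f"{int(m)}g_{int(d)}ms": row.to_dict() for (m, d), row in cond.iterrows()
        }
    bias_path = outdir / "bias_summary.csv"
    if bias_path.exists():
        bias = pd.read_csv(bias_path)
        if not bias.empty:
            report["perception"] = {
                "mean_total_bias_pct": float(bias["total_bias_pct"].mean()),
                "n_participants": len(bias),
            }
    agg_path = outdir / "model_aggregate.csv"
    if agg_path.exists():
        agg = pd.read_csv(agg_path)
        report["models"] = agg.round(6).to_dict(orient="records")

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _log(outdir, "report", {"written": "report.json"})
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "process": stage_process,
    "psych": stage_psych,
    "modelfit": stage_modelfit,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Execute the requested stages in canonical order; returns per-stage
    log payloads.  A stage failure raises after logging the cause."""
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    results = {}
    for stage in chosen:
        try:
            results[stage] = _STAGE_FUNCS[stage](cfg)
        except Exception as err:
            _log(Path(cfg.outdir), stage, {"error": f"{type(err).__name__}: {err}"})
            raise
    return results
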