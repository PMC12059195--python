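"""End-to-end orchestration: simulate -> qc -> strain -> activity -> geo ->
models -> report.

Each stage is a pure function over the in-memory study bundle; ``run_pipeline``
chains them and writes the canonical CSV/JSON report bundle plus a run
manifest with record counts in/out per stage, so conservation
(records_in == records_out + records_rejected) is auditable from the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import qc as qcmod
from .activity import (ActivityCutpoints, classify_intensity,
                       daily_activity_summary, detect_sleep_windows,
                       sleep_metrics)
from .core import Device, EpochGrid, SensorSeries, device_specs
from .geo import Geofence, classify_waypoints, track_summary
from .models import (fit_metric_by_sex_lme, fit_psi_wbgt_lme, LMEFit,
                     social_experience_table, summarize_likert,
                     wbgt_location_daynight)
from .strain import (StrainParameters, daily_strain_summary, diurnal_profile,
                     resting_baselines, reserve_capacities, strain_series,
                     summary_by_sex)
from .synthetic import CohortSpec, SimulatedStudy, simulate_study

log = logging.getLogger("heatwear.pipeline")


@dataclass
class QCResult:
    clean_hr: dict[str, SensorSeries]
    clean_cbt: dict[str, SensorSeries]
    ledger: pd.DataFrame
    feasibility: pd.DataFrame
    availabilities: dict[Device, float]
    counts: dict[str, int]


def run_qc(study: SimulatedStudy) -> QCResult:
    """Plausibility-filter HR/CBT and compute the feasibility report."""
    cfg = study.spec.config
    rules = qcmod.default_rules(cfg["qc"])
    params = StrainParameters.from_config(cfg["strain"])
    specs = device_specs(cfg["devices"])
    clean_hr, clean_cbt = {}, {}
    ledgers = []
    records = []
    n_in = n_out = 0
    for pid, prof in study.profiles.items():
        for device, store, raw in ((Device.HR, clean_hr, study.hr.get(pid)),
                                   (Device.CBT, clean_cbt, study.cbt.get(pid))):
            if raw is None:
                continue
            clean, rejected = qcmod.apply_plausibility_filters(raw, prof, rules, params)
            n_in += len(raw)
            n_out += len(clean)
            store[pid] = clean
            if len(rejected):
                rejected.insert(0, "unit_id", pid)
                rejected.insert(1, "device", device.value)
                ledgers.append(rejected)
            records.append(qcmod.data_completeness(clean, specs[device]))
        act = study.act.get(pid)
        if act is not None:
            records.append(qcmod.data_completeness(act, specs[Device.ACT]))
        gps = study.gps.get(pid)
        if gps is not None:
            gps_series = SensorSeries(Device.GPS, gps, participant_id=pid)
            records.append(qcmod.data_completeness(gps_series, specs[Device.GPS]))
    for hid, series in study.indoor.items():
        records.append(qcmod.data_completeness(series, specs[Device.WBGT_INDOOR]))

    n_participants = len(study.profiles)
    n_households = len(study.households)
    availabilities: dict[Device, float] = {}
    for device in (Device.HR, Device.CBT, Device.ACT, Device.GPS):
        usable = sum(1 for r in records
                     if r.device is device and r.usable_hours > 0)
        availabilities[device] = qcmod.data_availability(usable, n_participants)
    usable_w = sum(1 for r in records
                   if r.device is Device.WBGT_INDOOR and r.usable_hours > 0)
    availabilities[Device.WBGT_INDOOR] = qcmod.data_availability(usable_w, n_households)

    # only units that returned >= 1 usable recording enter the distribution
    feas = qcmod.summarize_feasibility([r for r in records if r.usable_hours > 0],
                                       availabilities)
    ledger = (pd.concat(ledgers, ignore_index=True) if ledgers
              else pd.DataFrame(columns=["unit_id", "device", "timestamp",
                                         "value", "rule", "reason"]))
    counts = {"records_in": n_in, "records_out": n_out,
              "records_rejected": int(n_in - n_out)}
    return QCResult(clean_hr, clean_cbt, ledger, feas, availabilities, counts)


@dataclass
class StrainResult:
    per_epoch: dict[str, pd.DataFrame]
    reserves: dict[str, Any]
    per_participant: pd.DataFrame
    by_sex: pd.DataFrame
    diurnal: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def run_strain(study: SimulatedStudy, qc_result: QCResult) -> StrainResult:
    """Baselines, reserves and per-epoch strain for every usable participant."""
    cfg = study.spec.config
    params = StrainParameters.from_config(cfg["strain"])
    grid = EpochGrid(int(cfg["strain"]["epoch_min"]))
    per_epoch, reserves = {}, {}
    skipped = []
    for pid, prof in study.profiles.items():
        hr = qc_result.clean_hr.get(pid)
        cbt = qc_result.clean_cbt.get(pid)
        if hr is None or cbt is None or len(hr) == 0 or len(cbt) == 0:
            skipped.append(pid)
            continue
        rhr, t0 = resting_baselines(hr, cbt, grid)
        res = reserve_capacities(prof, rhr, t0, params)
        reserves[pid] = res
        per_epoch[pid] = strain_series(hr, cbt, res, params, grid)
    per_participant = daily_strain_summary(per_epoch)
    by_sex = summary_by_sex(per_participant, study.profiles) if len(per_participant) else pd.DataFrame()
    diurnal = diurnal_profile(per_epoch, study.profiles) if per_epoch else pd.DataFrame()
    return StrainResult(per_epoch, reserves, per_participant, by_sex, diurnal, skipped)


@dataclass
class ActivityResult:
    labeled: dict[str, pd.DataFrame]
    daily: dict[str, pd.DataFrame]
    sleep_records: dict[str, list]
    per_participant: pd.DataFrame
    trends: pd.DataFrame


def run_activity(study: SimulatedStudy) -> ActivityResult:
    cfg = study.spec.config["activity"]
    cuts = ActivityCutpoints.from_config(study.spec.config["activity"])
    labeled, daily, sleep_recs = {}, {}, {}
    rows = []
    trend_rows = []
    for pid, series in study.act.items():
        if len(series) == 0:
            continue
        lab = classify_intensity(series.data, cuts)
        labeled[pid] = lab
        day_sum = daily_activity_summary(lab, epoch_s=float(cfg["epoch_s"]))
        daily[pid] = day_sum
        recs = detect_sleep_windows(lab, sleep_threshold=float(cfg["sleep_threshold"]),
                                    cutpoints=cuts)
        sleep_recs[pid] = recs
        met = sleep_metrics(recs)
        sex = study.profiles[pid].sex
        rows.append({"participant_id": pid, "sex": sex,
                     "mean_mvpa_hours": day_sum["mvpa_hours"].mean(),
                     "mean_daily_steps": day_sum["steps"].mean(),
                     "mean_daily_distance_km": day_sum["distance_km"].mean(),
                     **met})
        start = study.spec.start
        for _, r in day_sum.iterrows():
            trend_rows.append({"participant_id": pid, "sex": sex,
                               "day_index": (r["date"] - start).days + 1,
                               "mvpa_hours": r["mvpa_hours"], "steps": r["steps"]})
        for rec in recs:
            trend_rows.append({"participant_id": pid, "sex": sex,
                               "day_index": (rec.night - start).days + 1,
                               "sleep_h": rec.total_sleep_h,
                               "bed_h": rec.time_in_bed_h,
                               "efficiency_pct": rec.efficiency_pct})
    per_participant = pd.DataFrame(rows)
    trends = pd.DataFrame(trend_rows)
    if len(trends):
        trends = (trends.groupby(["day_index", "sex"]).mean(numeric_only=True)
                  .reset_index())
    return ActivityResult(labeled, daily, sleep_recs, per_participant, trends)


def run_geo(study: SimulatedStudy) -> pd.DataFrame:
    """Label every participant's track and summarise distance / time-by-place."""
    rows = []
    g = study.spec.config["gps"]
    for pid, track in study.gps.items():
        if len(track) == 0:
            continue
        hid = study.profiles[pid].household_id
        home_fence = Geofence(study.homes[hid], float(g["home_radius_m"]), "home")
        lab = classify_waypoints(track, home_fence, study.farms[hid])
        summ = track_summary(lab)
        rows.append({"participant_id": pid, "distance_km": summ.distance_km,
                     "home_h": summ.time_by_label_h.get("home", 0.0),
                     "farm_h": summ.time_by_label_h.get("farm", 0.0),
                     "elsewhere_h": summ.time_by_label_h.get("elsewhere", 0.0),
                     "unobserved_h": summ.unobserved_h})
    return pd.DataFrame(rows)


def build_psi_model_table(study: SimulatedStudy, strain_result: StrainResult,
                          activity_result: ActivityResult) -> pd.DataFrame:
    """Assemble the PSI ~ WBGT long table from pipeline outputs.

    One row per complete 5-min strain epoch: outdoor WBGT interpolated to
    the epoch, the day's MVPA total, the previous night's sleep (the night
    ending on the epoch's date) and the participant's anthropometry.
    """
    out = study.outdoor.data
    osec = out["timestamp"].astype("int64").to_numpy() / 1e9
    rows = []
    for pid, df in strain_result.per_epoch.items():
        prof = study.profiles[pid]
        comp = df[df["complete"]].copy()
        if len(comp) == 0:
            continue
        tsec = comp["timestamp"].astype("int64").to_numpy() / 1e9
        comp["wbgt"] = np.interp(tsec, osec, out["value"].to_numpy())
        date = comp["timestamp"].dt.normalize()
        daily = activity_result.daily.get(pid)
        mvpa_by_date = (daily.set_index("date")["mvpa_hours"].to_dict()
                        if daily is not None else {})
        sleep_by_date = {rec.night: rec.total_sleep_h
                         for rec in activity_result.sleep_records.get(pid, [])}
        comp["mvpa_hours"] = date.map(mvpa_by_date)
        comp["sleep_hours"] = date.map(sleep_by_date)
        comp["participant_id"] = pid
        comp["sex"] = prof.sex
        comp["bmi"] = prof.bmi
        comp["fat_mass_pct"] = prof.fat_mass_pct
        rows.append(comp[["participant_id", "timestamp", "sex", "psi", "wbgt",
                          "mvpa_hours", "sleep_hours", "bmi", "fat_mass_pct"]])
    if not rows:
        return pd.DataFrame()
    table = pd.concat(rows, ignore_index=True)
    return table.dropna(subset=["mvpa_hours", "sleep_hours", "fat_mass_pct"])


@dataclass
class ModelsResult:
    wbgt: dict[str, pd.DataFrame]
    psi_sex_fit: LMEFit | None
    psi_wbgt_fit: LMEFit | None
    likert: pd.DataFrame
    likert_by_sex: pd.DataFrame
    social: pd.DataFrame


def run_models(study: SimulatedStudy, strain_result: StrainResult,
               activity_result: ActivityResult) -> ModelsResult:
    wbgt = wbgt_location_daynight(study.indoor, study.outdoor)
    psi_sex_fit = psi_wbgt_fit = None
    if len(strain_result.per_epoch) >= 4:
        frames = []
        for pid, df in strain_result.per_epoch.items():
            comp = df[df["complete"]]
            frames.append(pd.DataFrame({
                "participant_id": pid, "sex": study.profiles[pid].sex,
                "value": comp["psi"], "timestamp": comp["timestamp"]}))
        long = pd.concat(frames, ignore_index=True)
        try:
            psi_sex_fit = fit_metric_by_sex_lme(long)
        except (ValueError, np.linalg.LinAlgError):
            psi_sex_fit = None
        table = build_psi_model_table(study, strain_result, activity_result)
        if len(table) and table["participant_id"].nunique() >= 4:
            try:
                psi_wbgt_fit = fit_psi_wbgt_lme(table)
            except (ValueError, np.linalg.LinAlgError):
                log.warning("PSI~WBGT fit failed on this cohort; omitted")
                psi_wbgt_fit = None
    likert = summarize_likert(study.likert)
    likert_sex = summarize_likert(study.likert, stratify_by_sex=True)
    social = (social_experience_table(study.social) if len(study.social)
              else pd.DataFrame())
    return ModelsResult(wbgt, psi_sex_fit, psi_wbgt_fit, likert, likert_sex, social)


# ---------------------------------------------------------------------------
# report bundle


def _fit_to_dict(fit: LMEFit | None) -> dict | None:
    if fit is None:
        return None
    return {"params": fit.params.to_dict(orient="records"),
            "random_intercept_sd": fit.random_intercept_sd,
            "residual_sd": fit.residual_sd, "n_obs": fit.n_obs,
            "n_groups": fit.n_groups, "converged": fit.converged}


def run_pipeline(config: dict, seed: int, outdir: str | Path,
                 include_gps: bool = True) -> dict[str, Any]:
    """Run every stage on a fresh simulated study and write the report bundle.

    Deterministic given (config, seed). Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(config, seed=seed)
    log.info("simulating cohort: %d pairs, %d days, seed %d",
             spec.n_pairs, spec.n_days, seed)
    study = simulate_study(spec, include_gps=include_gps)
    qc_result = run_qc(study)
    log.info("qc: %s", qc_result.counts)
    strain_result = run_strain(study, qc_result)
    activity_result = run_activity(study)
    geo_table = run_geo(study) if include_gps else pd.DataFrame()
    models_result = run_models(study, strain_result, activity_result)

    qc_result.feasibility.to_csv(outdir / "feasibility.csv", index=False)
    qc_result.ledger.to_csv(outdir / "qc_ledger.csv", index=False)
    strain_result.per_participant.to_csv(outdir / "strain_by_participant.csv",
                                         index=False)
    if len(strain_result.by_sex):
        strain_result.by_sex.to_csv(outdir / "strain_summary_by_sex.csv", index=False)
    if len(strain_result.diurnal):
        strain_result.diurnal.to_csv(outdir / "diurnal_profile.csv", index=False)
    activity_result.per_participant.to_csv(outdir / "activity_sleep_by_participant.csv",
                                           index=False)
    if len(activity_result.trends):
        activity_result.trends.to_csv(outdir / "daily_trends.csv", index=False)
    if len(geo_table):
        geo_table.to_csv(outdir / "gps_track_summaries.csv", index=False)
    for name, df in models_result.wbgt.items():
        df.to_csv(outdir / f"wbgt_{name}.csv", index=False)
    models_result.likert.to_csv(outdir / "likert_overall.csv", index=False)
    models_result.likert_by_sex.to_csv(outdir / "likert_by_sex.csv", index=False)
    if len(models_result.social):
        models_result.social.to_csv(outdir / "social_experience.csv", index=False)
    fits = {"psi_by_sex": _fit_to_dict(models_result.psi_sex_fit),
            "psi_by_wbgt": _fit_to_dict(models_result.psi_wbgt_fit)}
    (outdir / "model_fits.json").write_text(json.dumps(fits, indent=2, default=str))

    manifest = {
        "seed": seed,
        "n_pairs": spec.n_pairs,
        "n_days": spec.n_days,
        "stages": {
            "qc": qc_result.counts,
            "strain": {"participants_in": len(study.profiles),
                       "participants_out": len(strain_result.per_epoch),
                       "participants_rejected": len(strain_result.skipped)},
            "activity": {"participants": len(activity_result.labeled)},
            "geo": {"tracks": int(len(geo_table))},
        },
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
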