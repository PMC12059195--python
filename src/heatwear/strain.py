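"""Cardiac strain, thermal strain and the Physiological Strain Index.

Definitions
-----------
Resting heart rate (RHR) is the minimum epoch-averaged heart rate over the
wearing period, and the baseline core temperature T0 is the minimum
epoch-averaged CBT. Reserves are

    HRR  = HRmax(age) - RHR        (Tanaka age-predicted peak, 208 - 0.7 age)
    CBTr = Tcrit - T0              (critical core temperature, 39.5 degC)

Per epoch, cardiac strain = 100 (HR - RHR) / HRR percent, thermal strain =
100 (CBT - T0) / CBTr percent, and the Physiological Strain Index weights
each component by 5:

    PSI = 5 (cardiac + thermal) / 100,   on a 0-10 scale.

PSI is clamped to [0, 10] by default (field heart rates can exceed the
age-predicted peak); unclamped components are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochGrid, ParticipantProfile, SensorSeries, epoch_average


@dataclass(frozen=True)
class StrainParameters:
    critical_cbt: float = 39.5        # degC
    component_weight: float = 5.0
    scale_bounds: tuple[float, float] = (0.0, 10.0)
    tanaka_intercept: float = 208.0   # bpm
    tanaka_slope: float = -0.7        # bpm / year
    clamp: bool = True

    @staticmethod
    def from_config(cfg_strain: dict) -> "StrainParameters":
        return StrainParameters(
            critical_cbt=float(cfg_strain["critical_cbt"]),
            component_weight=float(cfg_strain["component_weight"]),
            scale_bounds=tuple(cfg_strain["scale_bounds"]),
            tanaka_intercept=float(cfg_strain["tanaka_intercept"]),
            tanaka_slope=float(cfg_strain["tanaka_slope"]),
            clamp=bool(cfg_strain["clamp"]),
        )


@dataclass(frozen=True)
class ReserveCapacities:
    rhr: float             # resting heart rate, bpm
    predicted_peak: float  # age-predicted maximum HR, bpm
    resting_cbt: float     # baseline (nadir) core temperature, degC
    critical_cbt: float

    @property
    def hrr(self) -> float:
        return self.predicted_peak - self.rhr

    @property
    def cbt_reserve(self) -> float:
        return self.critical_cbt - self.resting_cbt


class InsufficientDataError(ValueError):
    pass


def tanaka_max_hr(age: float, params: StrainParameters = StrainParameters()) -> float:
    """Age-predicted maximum heart rate, ``intercept + slope * age`` bpm."""
    if not 0 < age < 120:
        raise ValueError(f"age {age} outside (0, 120)")
    return params.tanaka_intercept + params.tanaka_slope * age


def resting_baselines(
    hr: SensorSeries, cbt: SensorSeries, grid: EpochGrid = EpochGrid()
) -> tuple[float, float]:
    """(RHR, resting CBT): minima of the epoch-averaged clean series.

    Computing the minimum on the averaging grid rather than on raw samples
    suppresses residual single-sample artifacts.
    """
    if len(hr) == 0 or len(cbt) == 0:
        raise InsufficientDataError("empty series after QC; no baseline defined")
    rhr = float(epoch_average(hr, grid).data["value"].min())
    t0 = float(epoch_average(cbt, grid).data["value"].min())
    return rhr, t0


def reserve_capacities(
    profile: ParticipantProfile,
    rhr: float,
    resting_cbt: float,
    params: StrainParameters = StrainParameters(),
) -> ReserveCapacities:
    peak = tanaka_max_hr(profile.age, params)
    if rhr >= peak:
        raise ValueError(f"degenerate participant: RHR {rhr} >= predicted peak {peak}")
    if resting_cbt >= params.critical_cbt:
        raise ValueError(
            f"degenerate participant: resting CBT {resting_cbt} >= critical "
            f"{params.critical_cbt}"
        )
    return ReserveCapacities(rhr, peak, resting_cbt, params.critical_cbt)


def strain_series(
    hr: SensorSeries,
    cbt: SensorSeries,
    reserves: ReserveCapacities,
    params: StrainParameters = StrainParameters(),
    grid: EpochGrid = EpochGrid(),
) -> pd.DataFrame:
    """Per-epoch strain table.

    HR and CBT are epoch-averaged onto the same grid and outer-joined.
    Columns: ``timestamp, hr, cbt, cardiac, thermal, psi, complete``.
    Epochs present in only one stream carry their single component and
    ``complete=False``; their PSI is NaN.
    """
    if reserves.hrr <= 0 or reserves.cbt_reserve <= 0:
        raise ValueError("degenerate reserves: HRR and CBT reserve must be positive")
    hr_e = epoch_average(hr, grid).data.rename(columns={"value": "hr"})
    cbt_e = epoch_average(cbt, grid).data.rename(columns={"value": "cbt"})
    df = hr_e.merge(cbt_e, on="timestamp", how="outer").sort_values("timestamp")
    df["cardiac"] = 100.0 * (df["hr"] - reserves.rhr) / reserves.hrr
    df["thermal"] = 100.0 * (df["cbt"] - reserves.resting_cbt) / reserves.cbt_reserve
    w = params.component_weight
    df["psi"] = w * (df["cardiac"] + df["thermal"]) / 100.0
    if params.clamp:
        lo, hi = params.scale_bounds
        df["psi"] = df["psi"].clip(lo, hi)
    df["complete"] = df["hr"].notna() & df["cbt"].notna()
    return df.reset_index(drop=True)


def daily_strain_summary(
    strains: dict[str, pd.DataFrame], sd_ddof: int = 1
) -> pd.DataFrame:
    """Per-participant strain summary (one row each).

    CV of HR is 100*SD/mean with the sample (n-1) standard deviation;
    peaks are the maxima of the clean epoch series; means of cardiac and
    thermal strain and PSI are taken over complete epochs.
    """
    rows = []
    for pid, df in strains.items():
        hrv = df["hr"].dropna()
        cbtv = df["cbt"].dropna()
        comp = df[df["complete"]]
        rows.append({
            "participant_id": pid,
            "mean_hr": hrv.mean(),
            "cv_hr_pct": 100.0 * hrv.std(ddof=sd_ddof) / hrv.mean() if len(hrv) > 1 else 0.0,
            "peak_hr": hrv.max(),
            "mean_cbt": cbtv.mean(),
            "peak_cbt": cbtv.max(),
            "mean_cardiac_pct": comp["cardiac"].mean(),
            "mean_thermal_pct": comp["thermal"].mean(),
            "mean_psi": comp["psi"].mean(),
        })
    return pd.DataFrame(rows)


def summary_by_sex(per_participant: pd.DataFrame,
                   profiles: dict[str, ParticipantProfile]) -> pd.DataFrame:
    """Mean +/- SD of each per-participant metric, by sex."""
    df = per_participant.copy()
    df["sex"] = df["participant_id"].map(lambda p: profiles[p].sex)
    metrics = [c for c in df.columns if c not in ("participant_id", "sex")]
    agg = df.groupby("sex")[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def diurnal_profile(
    strains: dict[str, pd.DataFrame],
    profiles: dict[str, ParticipantProfile] | None = None,
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Hour-of-day means of cardiac strain, thermal strain and PSI.

    Returns up to 24 rows per stratum (hours with no data are absent);
    strata are sexes when profiles are given and ``stratify_by_sex`` is set.
    """
    frames = []
    for pid, df in strains.items():
        sub = df[df["complete"]].copy()
        sub["hour"] = sub["timestamp"].dt.hour
        if stratify_by_sex and profiles is not None:
            sub["stratum"] = profiles[pid].sex
        else:
            sub["stratum"] = "all"
        frames.append(sub[["stratum", "hour", "cardiac", "thermal", "psi"]])
    allf = pd.concat(frames, ignore_index=True)
    out = (allf.groupby(["stratum", "hour"])[["cardiac", "thermal", "psi"]]
           .mean().reset_index())
    return out
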