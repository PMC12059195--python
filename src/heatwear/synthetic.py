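"""Synthetic wearable-cohort generator with retained ground truth.

Generates a complete desk-scale study — 24 married male-female pairs, 14
days of actigraphy and indoor WBGT, one 24-h HR/CBT day, one 22-h GPS day,
surveys — with every latent quantity (resting physiology, sleep windows,
activity states, waypoint labels, injected gaps and artifacts) recorded in
a :class:`TruthRecord` so downstream stages can be validated by recovery.

Calibration-by-construction: the physiology simulator scales its diurnal,
activity and heat uplift components so each participant's *mean* cardiac
and thermal strain (relative to their own true baselines) equals the
configured sex-specific targets; the environment simulator's sinusoid
mesors equal the configured daily means. The defaults in
``data/defaults.yaml`` therefore are the study conditions the analysis is
expected to reproduce.

Randomness uses a single root seed with per-participant, per-device
substreams (``numpy.random.SeedSequence`` spawn keys), so enlarging the
cohort never perturbs existing participants' draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Any

import numpy as np
import pandas as pd

from .core import Device, ParticipantProfile, SensorSeries
from .geo import Geofence, GeoPoint, classify_waypoints, haversine_distance
from .strain import StrainParameters, tanaka_max_hr

_SEX_CODE = {"female": 0, "male": 1}
_DEVICE_CODE = {d: i for i, d in enumerate(Device)}
_STREAM = {"cohort": 0, "environment": 1, "physiology": 2, "activity": 3,
           "gps": 4, "missingness": 5, "survey": 6, "lme": 7}


def _rng(seed: int, stream: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAM[stream], *map(int, keys)]))


@dataclass
class CohortSpec:
    """Full generator configuration plus the root seed.

    ``config`` is the nested dict from :func:`heatwear.config.load_config`;
    the defaults are the calibrated study conditions.
    """

    config: dict[str, Any]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @property
    def n_pairs(self) -> int:
        return int(self.config["cohort"]["n_pairs"])

    @property
    def n_days(self) -> int:
        return int(self.config["cohort"]["n_days"])

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.config["cohort"]["start_date"])

    @property
    def hr_cbt_day_start(self) -> pd.Timestamp:
        # clamp so short deployments still have an HR/CBT day inside them
        day = min(int(self.config["cohort"]["hr_cbt_day"]), self.n_days)
        return self.start + timedelta(days=day - 1)

    @staticmethod
    def default(seed: int = 0, n_pairs: int | None = None,
                n_days: int | None = None) -> "CohortSpec":
        from .config import default_config
        cfg = default_config()
        if n_pairs is not None:
            cfg["cohort"]["n_pairs"] = int(n_pairs)
        if n_days is not None:
            cfg["cohort"]["n_days"] = int(n_days)
        return CohortSpec(cfg, seed=seed)


@dataclass
class NightTruth:
    bed_start: pd.Timestamp
    bed_end: pd.Timestamp
    time_in_bed_h: float
    total_sleep_h: float


@dataclass
class TruthRecord:
    """Ground truth retained for recovery testing."""

    resting_hr: dict[str, float] = field(default_factory=dict)
    resting_cbt: dict[str, float] = field(default_factory=dict)
    sleep_nights: dict[str, list[NightTruth]] = field(default_factory=dict)
    activity_states: dict[str, pd.DataFrame] = field(default_factory=dict)
    mvpa_hours: dict[str, dict[Any, float]] = field(default_factory=dict)
    gps_labels: dict[str, pd.DataFrame] = field(default_factory=dict)
    gap_ledger: list[dict] = field(default_factory=list)
    artifact_ledger: list[dict] = field(default_factory=list)
    lme_fixed_effects: dict[str, float] = field(default_factory=dict)

    def gap_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gap_ledger)

    def artifact_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.artifact_ledger)


# ---------------------------------------------------------------------------
# cohort


def _pair_ids(i: int) -> tuple[str, str, str]:
    hid = f"H{i:02d}"
    return hid, f"{hid}F", f"{hid}M"


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, ParticipantProfile],
                                               dict[str, tuple[str, str]]]:
    """Draw profiles: one woman and one man per household, ages uniform."""
    lo, hi = spec.config["cohort"]["age_range"]
    phys = spec.config["physiology"]
    profiles: dict[str, ParticipantProfile] = {}
    households: dict[str, tuple[str, str]] = {}
    for i in range(1, spec.n_pairs + 1):
        hid, pid_f, pid_m = _pair_ids(i)
        for pid, sex in ((pid_f, "female"), (pid_m, "male")):
            rng = _rng(spec.seed, "cohort", i, _SEX_CODE[sex])
            p = phys[sex]
            age = int(rng.integers(lo, hi + 1))
            height = float(np.clip(rng.normal(p["height_mean"], p["height_sd"]), 140, 200))
            weight = float(np.clip(rng.normal(p["weight_mean"], p["weight_sd"]), 38, 110))
            fm = float(np.clip(rng.normal(p["fat_mass_mean"], p["fat_mass_sd"]), 3, 45))
            bmi = round(weight / (height / 100.0) ** 2, 1)
            profiles[pid] = ParticipantProfile(pid, sex, age, round(height, 1),
                                               round(weight, 1), bmi, hid,
                                               fat_mass_pct=round(fm, 1))
        households[hid] = (pid_f, pid_m)
    return profiles, households


# ---------------------------------------------------------------------------
# environment


def _sinusoid(hours: np.ndarray, mesor: float, amplitude: float,
              peak_hour: float) -> np.ndarray:
    return mesor + amplitude * np.cos(2.0 * np.pi * (hours - peak_hour) / 24.0)


def simulate_environment(spec: CohortSpec, n_days: int | None = None
                         ) -> tuple[dict[str, SensorSeries], SensorSeries]:
    """Sinusoid-plus-noise diurnal WBGT, 10-min cadence.

    Returns (indoor series per household, shared outdoor series). The
    outdoor sinusoid peaks mid-afternoon; indoor series lag it and sit a
    configured offset warmer, with a small between-household level shift.
    """
    n_days = spec.n_days if n_days is None else int(n_days)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    env = spec.config["environment"]
    cad = int(env["cadence_min"])
    n = n_days * 24 * 60 // cad
    ts = pd.date_range(spec.start, periods=n, freq=f"{cad}min")
    hours = ts.hour + ts.minute / 60.0
    o = env["outdoor"]
    rng = _rng(spec.seed, "environment", 0, 0)
    out_vals = _sinusoid(hours.to_numpy(), o["mesor"], o["amplitude"], o["peak_hour"])
    out_vals = out_vals + rng.normal(0.0, o["noise_sd"], size=n)
    outdoor = SensorSeries(Device.WBGT_OUTDOOR,
                           pd.DataFrame({"timestamp": ts, "value": out_vals}),
                           household_id="station")
    i = env["indoor"]
    indoor: dict[str, SensorSeries] = {}
    for k in range(1, spec.n_pairs + 1):
        hid, _, _ = _pair_ids(k)
        rng_h = _rng(spec.seed, "environment", k, 1)
        offset = rng_h.normal(0.0, i["household_sd"])
        vals = _sinusoid(hours.to_numpy(), i["mesor"] + offset, i["amplitude"],
                         i["peak_hour"])
        vals = vals + rng_h.normal(0.0, i["noise_sd"], size=n)
        indoor[hid] = SensorSeries(Device.WBGT_INDOOR,
                                   pd.DataFrame({"timestamp": ts, "value": vals}),
                                   household_id=hid)
    return indoor, outdoor


# ---------------------------------------------------------------------------
# actigraphy + sleep

_MAG_BINS = {
    "sleep": (0.004, 0.018),
    "wake_in_bed": (0.025, 0.075),
    "sedentary": (0.022, 0.078),
    "light": (0.085, 0.29),
    "moderate": (0.31, 0.88),
    "vigorous": (0.92, 1.80),
}
_LABEL_OF_STATE = {"sleep": "sedentary", "wake_in_bed": "sedentary",
                   "sedentary": "sedentary", "light": "light",
                   "moderate": "moderate", "vigorous": "vigorous"}


def _pair_index(profile: ParticipantProfile) -> int:
    return int(profile.household_id.lstrip("H"))


def simulate_actigraphy_sleep(
    profile: ParticipantProfile, spec: CohortSpec, n_days: int | None = None
) -> tuple[SensorSeries, list[NightTruth], pd.DataFrame]:
    """14 days of 60-s activity epochs plus the true nightly sleep windows.

    Magnitudes are drawn strictly inside the cut-point bin of each epoch's
    true state, so intensity classification with the matching cut-points
    recovers the state ledger exactly. Nightly in-bed windows contain short
    wake bouts sized so that true sleep time matches the configured
    efficiency; bouts stay shorter than the sleep detector's default bridge
    length. Returns (series, night truths, per-epoch state frame).
    """
    n_days = spec.n_days if n_days is None else int(n_days)
    act = spec.config["activity"]
    slp = spec.config["sleep"]
    sex = profile.sex
    rng = _rng(spec.seed, "activity", _pair_index(profile), _SEX_CODE[sex])
    epoch_s = int(act["epoch_s"])
    n = n_days * 24 * 3600 // epoch_s
    ts = pd.date_range(spec.start, periods=n, freq=f"{epoch_s}s")
    states = np.full(n, "sedentary", dtype=object)
    protected = np.zeros(n, dtype=bool)   # bed windows + buffers: day states keep out
    per_min = 60.0 / epoch_s

    mvpa_mean = float(np.clip(
        rng.normal(act["mvpa_hours_mean"][sex], act["mvpa_hours_sd"][sex]), 0.5, 7.0))
    nights: list[NightTruth] = []
    for d in range(n_days - 1):
        # keep the bed window inside the detector's default night search
        # window (20:00-10:00) so recovery is testable epoch-for-epoch
        start_frac = float(np.clip(rng.normal(slp["bed_start_hour_mean"],
                                              slp["bed_start_hour_sd"]), 20.3, 23.5))
        bed_start_h = 24.0 * d + start_frac
        dur_h = float(np.clip(rng.normal(slp["bed_hours_mean"][sex],
                                         slp["bed_hours_sd"]), 6.0, 11.0))
        dur_h = min(dur_h, 24.0 + 9.75 - start_frac)
        i0 = int(round(bed_start_h * 60 * per_min))
        i1 = min(int(round((bed_start_h + dur_h) * 60 * per_min)), n)
        states[i0:i1] = "sleep"
        eff = float(np.clip(rng.normal(slp["efficiency_mean"][sex],
                                       slp["efficiency_sd"]),
                            *slp["efficiency_range"]))
        wake_epochs = int(round((1.0 - eff) * (i1 - i0)))
        placed = 0
        guard = 0
        while placed < wake_epochs and guard < 1000:
            guard += 1
            blen = int(rng.integers(slp["wake_bout_min_epochs"],
                                    slp["wake_bout_max_epochs"] + 1))
            blen = min(blen, wake_epochs - placed)
            b0 = int(rng.integers(i0 + 5, max(i0 + 6, i1 - 5 - blen)))
            if (states[b0:b0 + blen] == "sleep").all():
                states[b0:b0 + blen] = "wake_in_bed"
                placed += blen
        n_sleep = int((states[i0:i1] == "sleep").sum())
        nights.append(NightTruth(ts[i0], ts[i1 - 1] + pd.Timedelta(seconds=epoch_s),
                                 (i1 - i0) * epoch_s / 3600.0,
                                 n_sleep * epoch_s / 3600.0))
        # buffer of light activity around the bed window so detection is exact
        buf = 21
        states[max(0, i0 - buf):i0] = "light"
        states[i1:min(n, i1 + buf)] = "light"
        protected[max(0, i0 - buf):min(n, i1 + buf)] = True

        # daytime structure for day d: MVPA in morning and early afternoon
        # (never overwriting a bed window that ran into the morning)
        day0 = int(24 * 60 * per_min * d)
        mvpa_h = float(np.clip(rng.normal(mvpa_mean, act["mvpa_day_jitter_h"]), 0.25, 8.0))
        m_epochs = int(round(mvpa_h * 60 * per_min))
        vig = int(round(0.15 * m_epochs))
        for frac, start_h in ((0.6, 8.0 + rng.uniform(-0.5, 0.5)),
                              (0.4, 12.5 + rng.uniform(-0.5, 0.5))):
            blk = int(round(frac * m_epochs))
            j0 = day0 + int(round(start_h * 60 * per_min))
            j1 = min(j0 + blk, n)
            free = ~protected[j0:j1]
            states[j0:j1][free] = "moderate"
        # vigorous epochs at the start of the morning block
        j0 = day0 + int(round(8.0 * 60 * per_min))
        mod_idx = np.where(states[j0:j0 + 4 * 60] == "moderate")[0]
        states[j0 + mod_idx[:vig]] = "vigorous"
        # light activity around midday
        l_h = float(np.clip(rng.normal(act["light_hours_mean"], act["light_hours_sd"]),
                            0.5, 6.0))
        j0 = day0 + int(round(10.5 * 60 * per_min))
        j1 = min(j0 + int(round(l_h * 60 * per_min)), n)
        sed = (states[j0:j1] == "sedentary") & ~protected[j0:j1]
        states[j0:j1][sed] = "light"

    # draw magnitudes inside each state's bin; steps proportional to intensity
    mag = np.empty(n)
    steps = np.zeros(n, dtype=int)
    for state, (lo, hi) in _MAG_BINS.items():
        m = states == state
        mag[m] = rng.uniform(lo, hi, size=int(m.sum()))
    for state, rate in act["steps_per_min"].items():
        m = states == state
        if rate > 0 and m.any():
            steps[m] = np.round(rate / per_min
                                * rng.uniform(0.8, 1.2, size=int(m.sum()))).astype(int)

    series = SensorSeries(Device.ACT,
                          pd.DataFrame({"timestamp": ts, "magnitude": mag,
                                        "steps": steps}),
                          participant_id=profile.participant_id)
    state_frame = pd.DataFrame({"timestamp": ts, "state": states})
    return series, nights, state_frame


def mvpa_truth_hours(state_frame: pd.DataFrame, epoch_s: float = 60.0) -> dict:
    """Ledger MVPA hours per calendar date (moderate + vigorous states)."""
    df = state_frame.copy()
    df["date"] = df["timestamp"].dt.date
    m = df["state"].isin(["moderate", "vigorous"])
    return (df[m].groupby("date").size() * epoch_s / 3600.0).to_dict()


# ---------------------------------------------------------------------------
# physiology


def _circadian_profile(hours: np.ndarray, peak: float, halfwidth: float) -> np.ndarray:
    c0 = np.cos(2.0 * np.pi * halfwidth / 24.0)
    raw = np.cos(2.0 * np.pi * (hours - peak) / 24.0) - c0
    return np.maximum(0.0, raw) / (1.0 - c0)


def _scaled_uplift(target_mean: float, components: dict[str, np.ndarray],
                   weights: dict[str, float]) -> np.ndarray:
    """Mix nonnegative shape components so the result has the target mean.

    Each component is scaled to contribute ``weight_k * target_mean`` to the
    time average; components that are identically ~0 drop out and their
    weight is redistributed over the others.
    """
    means = {k: float(v.mean()) for k, v in components.items()}
    active = {k: w for k, w in weights.items() if means.get(k, 0.0) > 1e-9}
    wsum = sum(active.values())
    total = np.zeros_like(next(iter(components.values())))
    for k, w in active.items():
        total = total + (w / wsum) * target_mean / means[k] * components[k]
    return total


def simulate_physiology(
    profile: ParticipantProfile,
    environment: SensorSeries,
    activity_states: pd.DataFrame,
    spec: CohortSpec,
    truth: TruthRecord | None = None,
) -> tuple[SensorSeries, SensorSeries]:
    """One 24-h day of 1-min HR and CBT samples.

    HR(t) = RHR + uplift(t) + noise, floored at the participant's true RHR,
    where the uplift mixes a single-harmonic circadian lobe, the activity
    intensity from the actigraphy state ledger, and outdoor-WBGT excess
    over a reference, scaled so the time-mean cardiac strain against the
    true baselines equals the sex-specific calibration target. CBT is
    built the same way around the true resting CBT with a later peak.
    """
    phys = spec.config["physiology"]
    p = phys[profile.sex]
    cad = int(phys["cadence_s"])
    t0 = spec.hr_cbt_day_start
    nsmp = 24 * 3600 // cad
    ts = pd.date_range(t0, periods=nsmp, freq=f"{cad}s")
    t_end = ts[-1]

    env = environment.data
    if env["timestamp"].iloc[0] > t0 or env["timestamp"].iloc[-1] < t_end - pd.Timedelta(minutes=10):
        raise ValueError("environment series does not cover the HR/CBT window")
    st = activity_states
    if st["timestamp"].iloc[0] > t0 or st["timestamp"].iloc[-1] < t_end:
        raise ValueError("activity series does not cover the HR/CBT window")

    rng = _rng(spec.seed, "physiology", _pair_index(profile), _SEX_CODE[profile.sex])
    rhr = float(np.clip(rng.normal(p["rhr_mean"], p["rhr_sd"]), 35.0, 80.0))
    t_rest = float(rng.normal(p["resting_cbt_mean"], p["resting_cbt_sd"]))
    peak_hr = tanaka_max_hr(profile.age, StrainParameters.from_config(spec.config["strain"]))

    hours = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy()
    tsec = ts.astype("int64").to_numpy() / 1e9
    esec = env["timestamp"].astype("int64").to_numpy() / 1e9
    wbgt = np.interp(tsec, esec, env["value"].to_numpy())
    heat = np.maximum(0.0, wbgt - float(phys["heat_reference_c"]))
    lvl = spec.config["activity"]["intensity_level"]
    state_at = st.set_index("timestamp")["state"].reindex(ts, method="ffill")
    intensity = state_at.map(lambda s: lvl[_intensity_key(s)]).to_numpy(dtype=float)

    def build(base, reserve, target_pct, peak_hour, halfwidth, weights, noise_sd):
        comps = {
            "circadian": _circadian_profile(hours, peak_hour, halfwidth),
            "activity": intensity,
            "heat": heat,
        }
        uplift = _scaled_uplift(target_pct / 100.0 * reserve, comps, weights)
        vals = base + uplift + rng.normal(0.0, noise_sd, size=nsmp)
        return np.maximum(vals, base)

    strain_cfg = spec.config["strain"]
    hr_vals = build(rhr, peak_hr - rhr, p["target_cardiac_pct"],
                    phys["hr_peak_hour"], phys["hr_halfwidth_h"],
                    phys["hr_weights"], phys["hr_noise_sd"])
    cbt_vals = build(t_rest, float(strain_cfg["critical_cbt"]) - t_rest,
                     p["target_thermal_pct"], phys["cbt_peak_hour"],
                     phys["cbt_halfwidth_h"], phys["cbt_weights"],
                     phys["cbt_noise_sd"])

    if truth is not None:
        truth.resting_hr[profile.participant_id] = rhr
        truth.resting_cbt[profile.participant_id] = t_rest
    hr = SensorSeries(Device.HR, pd.DataFrame({"timestamp": ts, "value": hr_vals}),
                      participant_id=profile.participant_id)
    cbt = SensorSeries(Device.CBT, pd.DataFrame({"timestamp": ts, "value": cbt_vals}),
                       participant_id=profile.participant_id)
    return hr, cbt


def _intensity_key(state: str) -> str:
    return {"wake_in_bed": "sedentary"}.get(state, state)


# ---------------------------------------------------------------------------
# GPS


def _offset_point(origin: GeoPoint, distance_km: float, bearing_deg: float) -> GeoPoint:
    from .geo import EARTH_RADIUS_KM
    brg = np.radians(bearing_deg)
    dlat = distance_km / EARTH_RADIUS_KM * np.cos(brg)
    dlon = distance_km / (EARTH_RADIUS_KM * np.cos(np.radians(origin.lat))) * np.sin(brg)
    return GeoPoint(origin.lat + np.degrees(dlat), origin.lon + np.degrees(dlon))


def simulate_gps_day(
    profile: ParticipantProfile,
    home: GeoPoint,
    farms: list[Geofence],
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One 22-h day of 1-min GPS fixes: home -> farm dwell -> home.

    The commute legs are straight great-circle walks to the first farm's
    centre, sized so the cumulative track length equals the configured
    round-trip route length; dwell fixes are stationary unless fix noise is
    configured. Returns (track, truth labels), where true labels are the
    geofence labels of the noiseless positions.
    """
    g = spec.config["gps"]
    home_fence = Geofence(home, float(g["home_radius_m"]), "home")
    for fence in farms:
        gap_m = haversine_distance(home, fence.center) * 1000.0
        if gap_m <= home_fence.radius_m + fence.radius_m:
            warnings.warn(f"farm fence at {gap_m:.0f} m overlaps the home buffer; "
                          "home label takes precedence", stacklevel=2)
    farm = farms[0].center if farms else _offset_point(
        home, float(g["farm_distance_km"]), float(g["farm_bearing_deg"]))

    fix_s = int(g["fix_interval_s"])
    n = int(float(g["duration_h"]) * 3600 // fix_s)
    day0 = spec.hr_cbt_day_start
    ts = pd.date_range(day0, periods=n, freq=f"{fix_s}s")

    leg_km = haversine_distance(home, farm)
    walk_fixes = max(2, int(round(leg_km * 1000.0 / float(g["walk_speed_ms"]) / fix_s)))
    dwell_fixes = int(float(g["farm_dwell_h"]) * 3600 // fix_s)
    depart = int(8.0 * 3600 // fix_s)         # leave home at 08:00

    lat = np.full(n, home.lat)
    lon = np.full(n, home.lon)
    seg = slice(depart, depart + walk_fixes)
    frac = np.linspace(0.0, 1.0, walk_fixes)
    lat[seg] = home.lat + frac * (farm.lat - home.lat)
    lon[seg] = home.lon + frac * (farm.lon - home.lon)
    d0 = depart + walk_fixes
    lat[d0:d0 + dwell_fixes] = farm.lat
    lon[d0:d0 + dwell_fixes] = farm.lon
    r0 = d0 + dwell_fixes
    seg = slice(r0, r0 + walk_fixes)
    lat[seg] = farm.lat + frac * (home.lat - farm.lat)
    lon[seg] = farm.lon + frac * (home.lon - farm.lon)

    track = pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})
    truth_labels = classify_waypoints(track, home_fence,
                                      farms or [Geofence.from_area(farm, g["farm_area_acres"], "farm")])
    noise_m = float(g["noise_sd_m"])
    if noise_m > 0:
        rng = _rng(spec.seed, "gps", _pair_index(profile), _SEX_CODE[profile.sex])
        track = track.copy()
        track["lat"] += rng.normal(0, noise_m / 111_195.0, size=n)
        track["lon"] += rng.normal(0, noise_m / 111_195.0, size=n)
    return track, truth_labels[["timestamp", "label"]]


# ---------------------------------------------------------------------------
# missingness and artifacts


def inject_missingness_and_artifacts(
    series: SensorSeries,
    spec: CohortSpec,
    truth: TruthRecord,
    profile: ParticipantProfile | None = None,
    unit_key: int = 0,
) -> SensorSeries:
    """Degrade a pristine series per the device's missingness calibration.

    Whole-recording failures and gap intervals remove rows; implausible
    spikes (HR outside [40, predicted max], CBT outside [35, 42]) replace
    values. Every removal and insertion is appended to the truth ledgers.
    """
    dev = series.device
    miss = spec.config["missingness"].get(dev.value)
    rng = _rng(spec.seed, "missingness", unit_key, _DEVICE_CODE[dev])
    uid = series.unit_id
    data = series.data

    if miss is not None:
        if rng.uniform() < miss["failure_prob"]:
            truth.gap_ledger.append({"unit_id": uid, "device": dev.value,
                                     "kind": "failure", "start": data["timestamp"].iloc[0]
                                     if len(data) else None, "end": None,
                                     "n_samples": len(data)})
            return series.with_data(data.iloc[0:0])
        if len(data) and rng.uniform() < miss["gap_prob"]:
            a, b = miss["gap_frac_beta"]
            frac = float(rng.beta(a, b))
            k = int(rng.integers(1, miss["max_gaps"] + 1))
            parts = rng.dirichlet(np.ones(k)) * frac
            t_first = data["timestamp"].iloc[0]
            t_last = data["timestamp"].iloc[-1]
            span = (t_last - t_first).total_seconds()
            keep = np.ones(len(data), dtype=bool)
            tsec = data["timestamp"].astype("int64").to_numpy() / 1e9
            for part in parts:
                glen = part * span
                gstart = tsec[0] + rng.uniform(0.0, max(span - glen, 1.0))
                m = (tsec >= gstart) & (tsec < gstart + glen)
                removed = int((m & keep).sum())
                keep &= ~m
                truth.gap_ledger.append({
                    "unit_id": uid, "device": dev.value, "kind": "gap",
                    "start": pd.Timestamp(gstart, unit="s"),
                    "end": pd.Timestamp(gstart + glen, unit="s"),
                    "n_samples": removed})
            data = data[keep].reset_index(drop=True)

    art = spec.config["artifacts"]
    rate = {Device.HR: art["hr_rate"], Device.CBT: art["cbt_rate"]}.get(dev, 0.0)
    if rate > 0 and len(data):
        data = data.copy()
        hit = rng.uniform(size=len(data)) < rate
        idx = np.where(hit)[0]
        for i in idx:
            original = float(data["value"].iloc[i])
            if dev is Device.HR:
                if rng.uniform() < 0.5:
                    bad = rng.uniform(*art["hr_low"])
                else:
                    if profile is None:
                        raise ValueError("HR artifact injection needs the profile (age)")
                    peak = tanaka_max_hr(profile.age,
                                         StrainParameters.from_config(spec.config["strain"]))
                    bad = peak + rng.uniform(*art["hr_high_above_max"])
            else:
                lohi = art["cbt_low"] if rng.uniform() < 0.5 else art["cbt_high"]
                bad = rng.uniform(*lohi)
            data.iloc[i, data.columns.get_loc("value")] = bad
            truth.artifact_ledger.append({
                "unit_id": uid, "device": dev.value,
                "timestamp": data["timestamp"].iloc[i],
                "injected_value": float(bad), "original_value": original})
    return series.with_data(data)


# ---------------------------------------------------------------------------
# surveys


LIKERT_ITEMS = ["positive_first_impression", "makes_no_sense", "strange_to_wear",
                "requires_attention", "cumbersome", "affects_routines", "likable"]
SOCIAL_QUESTIONS = ["people_asked_about_device", "device_topic_of_conversation"]
SURVEY_DEVICES = ["ECG", "CBT", "ACT", "GPS"]


def simulate_surveys(profiles: dict[str, ParticipantProfile],
                     spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likert responses (1=strongly agree .. 5=strongly disagree) per item x
    device, and binary social-experience responses for the configured
    subset of pairs."""
    sv = spec.config["surveys"]
    rng = _rng(spec.seed, "survey", 0, 0)
    p = np.array([sv["p_high"] / 2, sv["p_high"] / 2, sv["p_neutral"],
                  sv["p_low"] / 2, sv["p_low"] / 2])
    rows = []
    for pid, prof in profiles.items():
        for devname in SURVEY_DEVICES:
            for item in LIKERT_ITEMS:
                rows.append({"participant_id": pid, "sex": prof.sex,
                             "device": devname, "item": item,
                             "response": int(rng.choice([1, 2, 3, 4, 5], p=p))})
    likert = pd.DataFrame(rows)

    hids = sorted({prof.household_id for prof in profiles.values()})
    social_hids = set(hids[:int(sv["n_social_pairs"])])
    rows = []
    for pid, prof in profiles.items():
        if prof.household_id not in social_hids:
            continue
        for devname in SURVEY_DEVICES:
            for q in SOCIAL_QUESTIONS:
                yes = rng.uniform() < sv["p_social_yes"][prof.sex]
                rows.append({"participant_id": pid, "sex": prof.sex,
                             "device": devname, "question": q, "response": int(yes)})
    return likert, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSI mixed-model dataset


def simulate_psi_lme_dataset(
    truth_betas: dict[str, float],
    n_participants: int = 48,
    obs_per_participant: int = 144,
    random_intercept_sd: float = 0.5,
    residual_sd: float = 0.8,
    seed: int = 0,
    covariates: dict[str, Any] | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Long table drawn exactly from the PSI ~ WBGT mixed-effects model.

    One daytime 5-min epoch grid (06:30-18:30 gives 144 epochs) per
    participant; WBGT follows the default outdoor diurnal sinusoid with
    noise, the other covariates are per-participant draws from documented
    ranges. PSI = linear predictor + participant random intercept +
    Gaussian residual, with no censoring or clamping.
    """
    if random_intercept_sd < 0 or residual_sd < 0:
        raise ValueError("SDs must be nonnegative")
    from .config import default_config
    cfg = default_config()
    cov = covariates or cfg["lme_truth"]["covariates"]
    o = cfg["environment"]["outdoor"]
    rng = _rng(seed, "lme", 0, 0)

    day = pd.Timestamp(cfg["cohort"]["start_date"])
    ts = pd.date_range(day + pd.Timedelta(hours=6, minutes=30),
                       periods=obs_per_participant, freq="5min")
    hours = (ts.hour + ts.minute / 60.0).to_numpy()
    base_wbgt = _sinusoid(hours, o["mesor"], o["amplitude"], o["peak_hour"])

    b = truth_betas
    frames = []
    for i in range(n_participants):
        male = i % 2
        mvpa = float(np.clip(rng.normal(cov["mvpa_mean"], cov["mvpa_sd"]),
                             *cov["mvpa_range"]))
        sleep = float(np.clip(rng.normal(cov["sleep_mean"], cov["sleep_sd"]),
                              *cov["sleep_range"]))
        bmi = float(np.clip(rng.normal(cov["bmi_mean"], cov["bmi_sd"]), 15, 35))
        sexcfg = cfg["physiology"]["male" if male else "female"]
        fm = float(np.clip(rng.normal(sexcfg["fat_mass_mean"], sexcfg["fat_mass_sd"]),
                           3, 45))
        wbgt = base_wbgt + rng.normal(0.0, o["noise_sd"], size=obs_per_participant)
        b_i = rng.normal(0.0, random_intercept_sd)
        eps = rng.normal(0.0, residual_sd, size=obs_per_participant)
        psi = (b["beta0"] + b["sex_male"] * male + b["wbgt"] * wbgt
               + b["wbgt_sex"] * wbgt * male + b["mvpa"] * mvpa
               + b["sleep"] * sleep + b["bmi"] * bmi + b["fat_mass"] * fm
               + b_i + eps)
        frames.append(pd.DataFrame({
            "participant_id": f"P{i + 1:03d}", "timestamp": ts,
            "sex": "male" if male else "female", "male": male, "wbgt": wbgt,
            "mvpa_hours": mvpa, "sleep_hours": sleep, "bmi": bmi,
            "fat_mass_pct": fm, "psi": psi}))
    truth = TruthRecord(lme_fixed_effects=dict(b))
    truth.lme_fixed_effects["random_intercept_sd"] = random_intercept_sd
    truth.lme_fixed_effects["residual_sd"] = residual_sd
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# whole-study driver


@dataclass
class SimulatedStudy:
    spec: CohortSpec
    profiles: dict[str, ParticipantProfile]
    households: dict[str, tuple[str, str]]
    indoor: dict[str, SensorSeries]
    outdoor: SensorSeries
    hr: dict[str, SensorSeries]
    cbt: dict[str, SensorSeries]
    act: dict[str, SensorSeries]
    gps: dict[str, pd.DataFrame]
    homes: dict[str, GeoPoint]
    farms: dict[str, list[Geofence]]
    likert: pd.DataFrame
    social: pd.DataFrame
    truth: TruthRecord


def simulate_study(spec: CohortSpec, include_gps: bool = True) -> SimulatedStudy:
    """Generate the full study: cohort, environment, physiology, actigraphy,
    GPS and surveys, then apply the missingness/artifact model in place."""
    truth = TruthRecord()
    profiles, households = simulate_cohort(spec)
    indoor, outdoor = simulate_environment(spec)
    g = spec.config["gps"]

    hr, cbt, act, gps, homes, farms = {}, {}, {}, {}, {}, {}
    for hidx, (hid, (pid_f, pid_m)) in enumerate(sorted(households.items())):
        home = GeoPoint(float(g["home_lat"]),
                        float(g["home_lon"]) + hidx * float(g["home_spacing_deg"]))
        farm_center = _offset_point(home, float(g["farm_distance_km"]),
                                    float(g["farm_bearing_deg"]))
        hfarms = [Geofence.from_area(farm_center, float(g["farm_area_acres"]), "farm")]
        homes[hid] = home
        farms[hid] = hfarms
        for pid in (pid_f, pid_m):
            prof = profiles[pid]
            ukey = 2 * hidx + _SEX_CODE[prof.sex]
            series, nights, state_frame = simulate_actigraphy_sleep(prof, spec)
            truth.sleep_nights[pid] = nights
            truth.activity_states[pid] = state_frame
            truth.mvpa_hours[pid] = mvpa_truth_hours(state_frame)
            hr_s, cbt_s = simulate_physiology(prof, outdoor, state_frame, spec, truth)
            hr[pid] = inject_missingness_and_artifacts(hr_s, spec, truth, prof, ukey)
            cbt[pid] = inject_missingness_and_artifacts(cbt_s, spec, truth, prof, ukey)
            act[pid] = inject_missingness_and_artifacts(series, spec, truth, prof, ukey)
            if include_gps:
                track, labels = simulate_gps_day(prof, home, hfarms, spec)
                truth.gps_labels[pid] = labels
                gps_series = SensorSeries(Device.GPS, track, participant_id=pid)
                gps[pid] = inject_missingness_and_artifacts(
                    gps_series, spec, truth, prof, ukey).data
        indoor[hid] = inject_missingness_and_artifacts(indoor[hid], spec, truth,
                                                       None, hidx)
    likert, social = simulate_surveys(profiles, spec)
    return SimulatedStudy(spec, profiles, households, indoor, outdoor, hr, cbt,
                          act, gps, homes, farms, likert, social, truth)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the raw simulated study in canonical formats: per-participant
    sensor CSVs, per-household WBGT CSVs, GPX tracks, and the truth ledgers
    (CSV for the tabular ledgers, JSON for scalars)."""
    import json
    from pathlib import Path

    from .core import write_sensor_table
    from .geo import write_gpx

    outdir = Path(outdir)
    raw = outdir / "raw"
    truth_dir = outdir / "truth"
    raw.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    for pid in study.profiles:
        for store, tag in ((study.hr, "HR"), (study.cbt, "CBT"), (study.act, "ACT")):
            if pid in store:
                write_sensor_table(store[pid], raw / f"{pid}_{tag}.csv")
        if pid in study.gps and len(study.gps[pid]):
            write_gpx(study.gps[pid], raw / f"{pid}_GPS.gpx")
    for hid, series in study.indoor.items():
        write_sensor_table(series, raw / f"{hid}_WBGT_indoor.csv")
    write_sensor_table(study.outdoor, raw / "station_WBGT_outdoor.csv")
    study.likert.to_csv(raw / "likert_responses.csv", index=False)
    study.social.to_csv(raw / "social_responses.csv", index=False)

    profs = pd.DataFrame([vars(p) for p in study.profiles.values()])
    profs.to_csv(outdir / "profiles.csv", index=False)
    t = study.truth
    t.gap_frame().to_csv(truth_dir / "gap_ledger.csv", index=False)
    t.artifact_frame().to_csv(truth_dir / "artifact_ledger.csv", index=False)
    scalars = {"resting_hr": t.resting_hr, "resting_cbt": t.resting_cbt,
               "mvpa_hours": {pid: {str(k): v for k, v in d.items()}
                              for pid, d in t.mvpa_hours.items()},
               "lme_fixed_effects": t.lme_fixed_effects}
    (truth_dir / "truth.json").write_text(json.dumps(scalars, indent=2, default=str))
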