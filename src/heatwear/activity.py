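"""Actigraphy: intensity classification, daily activity and sleep metrics.

Epoch-level acceleration magnitudes (60-s epochs, g units) are classified
into sedentary / light / moderate / vigorous by half-open cut-point bins.
Cut-points are mandatory configuration — defaults ship in the package
config, with the moderate band starting at 0.30 and the vigorous band at
0.90 magnitude units.

Sleep is detected by a threshold-run rule: the in-bed window of a night is
the longest run of sub-cutpoint activity inside the night search window
(gaps up to a bridge length are tolerated); asleep epochs are those below a
stricter sleep threshold. Sleep efficiency is computed per night as
100 * total sleep time / time in bed, then averaged per participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time, timedelta

import numpy as np
import pandas as pd

STATES = ["sedentary", "light", "moderate", "vigorous"]


@dataclass(frozen=True)
class ActivityCutpoints:
    """Strictly increasing intensity thresholds, magnitude units."""

    sedentary_light: float = 0.08
    light_moderate: float = 0.30
    moderate_vigorous: float = 0.90
    provenance: str = "package default"

    def __post_init__(self) -> None:
        if not self.sedentary_light < self.light_moderate < self.moderate_vigorous:
            raise ValueError("cutpoints must be strictly increasing")

    @staticmethod
    def from_config(cfg_activity: dict) -> "ActivityCutpoints":
        c = cfg_activity["cutpoints"]
        return ActivityCutpoints(float(c["sedentary_light"]),
                                 float(c["light_moderate"]),
                                 float(c["moderate_vigorous"]),
                                 provenance="config")


@dataclass(frozen=True)
class SleepRecord:
    night: pd.Timestamp        # calendar date the night *ends* on
    bed_start: pd.Timestamp
    bed_end: pd.Timestamp
    time_in_bed_h: float
    total_sleep_h: float

    @property
    def efficiency_pct(self) -> float:
        if self.time_in_bed_h <= 0:
            return 0.0
        return 100.0 * self.total_sleep_h / self.time_in_bed_h


def classify_intensity(epochs: pd.DataFrame,
                       cutpoints: ActivityCutpoints = ActivityCutpoints()) -> pd.DataFrame:
    """Label each epoch with its intensity state.

    Bins are left-closed: [0, c1) sedentary, [c1, c2) light, [c2, c3)
    moderate, [c3, inf) vigorous. A magnitude exactly at a cut-point takes
    the higher label.
    """
    mag = epochs["magnitude"].to_numpy()
    if (mag < 0).any():
        raise ValueError("negative acceleration magnitude")
    edges = [cutpoints.sedentary_light, cutpoints.light_moderate,
             cutpoints.moderate_vigorous]
    idx = np.searchsorted(edges, mag, side="right")
    out = epochs.copy()
    out["state"] = np.asarray(STATES, dtype=object)[idx]
    return out


def daily_activity_summary(
    labeled: pd.DataFrame,
    epoch_s: float = 60.0,
    gps_km_by_day: dict | None = None,
    stride_m: float = 0.78,
) -> pd.DataFrame:
    """Per-day MVPA hours, step counts and distance.

    Distance comes from the GPS track summary when one is available for the
    day, otherwise from steps * stride length (default stride 0.78 m).
    """
    df = labeled.copy()
    df["date"] = df["timestamp"].dt.normalize()
    rows = []
    for date, day in df.groupby("date"):
        mvpa_h = (day["state"].isin(["moderate", "vigorous"]).sum()) * epoch_s / 3600.0
        steps = int(day["steps"].sum())
        key = date.date()
        if gps_km_by_day is not None and key in gps_km_by_day:
            dist, src = gps_km_by_day[key], "gps"
        else:
            dist, src = steps * stride_m / 1000.0, "steps"
        rows.append({"date": date, "mvpa_hours": mvpa_h, "steps": steps,
                     "distance_km": dist, "distance_source": src,
                     "worn_hours": len(day) * epoch_s / 3600.0})
    return pd.DataFrame(rows)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) index runs where mask is True."""
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_sleep_windows(
    labeled: pd.DataFrame,
    night_start: time = time(20, 0),
    night_end: time = time(10, 0),
    sleep_threshold: float = 0.02,
    bridge_epochs: int = 20,
    epoch_s: float = 60.0,
    min_bed_epochs: int = 60,
    cutpoints: ActivityCutpoints = ActivityCutpoints(),
) -> list[SleepRecord]:
    """Detect one in-bed window and its sleep time per night.

    For each night window (``night_start`` on day d to ``night_end`` on day
    d+1), the in-bed interval is the longest run of epochs whose magnitude
    is below the sedentary/light cut-point, after bridging above-threshold
    bouts of at most ``bridge_epochs`` epochs (brief awakenings stay in
    bed). Asleep epochs are in-bed epochs with magnitude below
    ``sleep_threshold``. Nights with no qualifying run (shorter than
    ``min_bed_epochs``) yield no record.
    """
    cut = cutpoints.sedentary_light
    df = labeled.sort_values("timestamp").reset_index(drop=True)
    ts = df["timestamp"]
    if len(df) == 0:
        return []
    records: list[SleepRecord] = []
    first_day = ts.iloc[0].normalize()
    last_day = ts.iloc[-1].normalize()
    day = first_day - timedelta(days=1)
    while day <= last_day:
        w0 = day + pd.Timedelta(hours=night_start.hour, minutes=night_start.minute)
        w1 = (day + timedelta(days=1)
              + pd.Timedelta(hours=night_end.hour, minutes=night_end.minute))
        window = df[(ts >= w0) & (ts < w1)]
        day += timedelta(days=1)
        if len(window) == 0:
            continue
        quiet = (window["magnitude"] < cut).to_numpy()
        # bridge short active bouts so brief awakenings do not split the window
        for s, e in _runs(~quiet):
            if e - s <= bridge_epochs and s > 0 and e < len(quiet):
                quiet[s:e] = True
        runs = _runs(quiet)
        if not runs:
            continue
        s, e = max(runs, key=lambda r: r[1] - r[0])
        if e - s < min_bed_epochs:
            continue
        in_bed = window.iloc[s:e]
        tib_h = len(in_bed) * epoch_s / 3600.0
        asleep = (in_bed["magnitude"] < sleep_threshold).sum()
        if asleep == 0:
            # quiet wake (reading, sitting) is not a sleep window
            continue
        records.append(SleepRecord(
            night=(in_bed["timestamp"].iloc[-1]).normalize(),
            bed_start=in_bed["timestamp"].iloc[0],
            bed_end=in_bed["timestamp"].iloc[-1] + pd.Timedelta(seconds=epoch_s),
            time_in_bed_h=tib_h,
            total_sleep_h=asleep * epoch_s / 3600.0,
        ))
    return records


def sleep_metrics(records: list[SleepRecord]) -> dict[str, float]:
    """Participant-level means: bedtime, sleep time, and per-night efficiency.

    Efficiency is averaged over nights (not the ratio of mean sleep to mean
    bed time); the two differ whenever nights vary in length.
    """
    if not records:
        return {"n_nights": 0, "mean_time_in_bed_h": float("nan"),
                "mean_total_sleep_h": float("nan"), "mean_efficiency_pct": float("nan")}
    return {
        "n_nights": len(records),
        "mean_time_in_bed_h": float(np.mean([r.time_in_bed_h for r in records])),
        "mean_total_sleep_h": float(np.mean([r.total_sleep_h for r in records])),
        "mean_efficiency_pct": float(np.mean([r.efficiency_pct for r in records])),
    }
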