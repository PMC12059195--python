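"""Plausibility filtering and feasibility metrics.

Usable data are what remain after removing corrupted rows (rejected at load
time) and implausible values: heart rate below 40 bpm or above the
participant's age-predicted maximum, and core temperature outside
35-42 degC. Feasibility is summarised by *data availability* (share of
units with at least one usable recording) and *data completeness* (share of
the device's intended recording time captured as usable data).

Bounds are inclusive: exactly 40 bpm or exactly 35.0 / 42.0 degC is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Device, DeviceSpec, ParticipantProfile, SensorSeries
from .strain import StrainParameters, tanaka_max_hr


@dataclass(frozen=True)
class QCRule:
    """Inclusive plausibility bounds for one device.

    ``upper`` may be the string ``"tanaka"`` to use the participant's
    age-predicted maximum heart rate as the bound.
    """

    device: Device
    lower: float
    upper: float | str

    def __post_init__(self) -> None:
        if isinstance(self.upper, (int, float)) and not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def bounds_for(self, profile: ParticipantProfile | None,
                   params: StrainParameters) -> tuple[float, float]:
        if self.upper == "tanaka":
            if profile is None:
                raise ValueError("per-participant HR bound requires a profile (age)")
            return self.lower, tanaka_max_hr(profile.age, params)
        return self.lower, float(self.upper)


def default_rules(cfg_qc: dict | None = None) -> dict[Device, QCRule]:
    cfg = cfg_qc or {"hr_lower": 40.0, "cbt_lower": 35.0, "cbt_upper": 42.0}
    return {
        Device.HR: QCRule(Device.HR, float(cfg["hr_lower"]), "tanaka"),
        Device.CBT: QCRule(Device.CBT, float(cfg["cbt_lower"]), float(cfg["cbt_upper"])),
    }


def apply_plausibility_filters(
    series: SensorSeries,
    profile: ParticipantProfile | None,
    rules: dict[Device, QCRule] | None = None,
    params: StrainParameters = StrainParameters(),
) -> tuple[SensorSeries, pd.DataFrame]:
    """Split a HR/CBT series into plausible samples and a rejection ledger.

    Returns ``(clean, rejected)`` with ``len(clean) + len(rejected) ==
    len(series)``. The ledger has columns ``timestamp, value, rule, reason``.
    """
    rules = rules if rules is not None else default_rules()
    if series.device not in rules:
        raise ValueError(f"no plausibility rule configured for {series.device.value}")
    rule = rules[series.device]
    if rule.device != series.device:
        raise ValueError("rule/device mismatch")
    lower, upper = rule.bounds_for(profile, params)
    values = series.data["value"]
    keep = (values >= lower) & (values <= upper)
    rejected = series.data.loc[~keep, ["timestamp", "value"]].copy()
    rejected["rule"] = f"{series.device.value}[{lower:g},{upper:g}]"
    rejected["reason"] = np.where(values[~keep] < lower, "below_lower", "above_upper")
    return series.with_data(series.data[keep]), rejected.reset_index(drop=True)


def data_availability(units_with_usable_data: int, total_units: int) -> float:
    """Percentage of units (participants or households) with >= 1 usable recording."""
    if total_units <= 0:
        raise ValueError("total_units must be positive")
    if not 0 <= units_with_usable_data <= total_units:
        raise ValueError("count must lie in [0, total_units]")
    return 100.0 * units_with_usable_data / total_units


@dataclass(frozen=True)
class CompletenessRecord:
    unit_id: str
    device: Device
    usable_hours: float
    intended_hours: float

    @property
    def completeness(self) -> float:
        """Usable share of the intended recording time, percent, capped at 100."""
        return min(100.0, 100.0 * self.usable_hours / self.intended_hours)


def usable_hours(series: SensorSeries, spec: DeviceSpec) -> float:
    """Union of per-sample coverage intervals, in hours.

    Each sample covers ``[t, t + nominal_interval)``; overlapping intervals
    (denser-than-nominal sampling) are merged, so irregular sampling never
    double-counts time.
    """
    if len(series) == 0:
        return 0.0
    t = series.data["timestamp"].astype("int64").to_numpy() / 1e9  # seconds
    dt = spec.nominal_interval_s
    starts, ends = t, t + dt
    total = 0.0
    cur_start, cur_end = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    return total / 3600.0


def data_completeness(series: SensorSeries, spec: DeviceSpec) -> CompletenessRecord:
    """Completeness of one (clean) recording against its intended duration."""
    return CompletenessRecord(series.unit_id, spec.device,
                              usable_hours(series, spec), spec.intended_hours)


def summarize_feasibility(
    records: list[CompletenessRecord],
    availabilities: dict[Device, float],
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Per-device feasibility table: availability plus the distribution of
    individual-level completeness (median, Q1, Q3, min, max).

    Quartiles use linear interpolation by default (numpy ``linear``,
    the common "type 7" convention); configurable because no convention is
    canonical for small samples. Devices with no records are omitted.
    """
    rows = []
    by_device: dict[Device, list[float]] = {}
    for rec in records:
        by_device.setdefault(rec.device, []).append(rec.completeness)
    for device, vals in by_device.items():
        arr = np.asarray(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method=quartile_method)
        rows.append({
            "device": device.value,
            "availability_pct": availabilities.get(device, np.nan),
            "n_units": len(arr),
            "completeness_median": med,
            "completeness_q1": q1,
            "completeness_q3": q3,
            "completeness_min": arr.min(),
            "completeness_max": arr.max(),
        })
    return pd.DataFrame(rows)
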