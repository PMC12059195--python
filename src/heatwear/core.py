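"""Canonical domain types and shared time-series primitives.

Every stage of the pipeline exchanges data through the types defined here:
participant profiles, device-tagged sensor series backed by pandas frames,
device deployment specs, and the 5-minute epoch grid. Timestamps are naive
local time throughout (all devices in the study design are clock-aligned to
local time), and gaps are represented by *absent rows*, never by NaN.

The canonical on-disk format is a comma-separated table with an ISO-8601
``timestamp`` column (seconds precision) and one or more value columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class Device(str, enum.Enum):
    """Kinds of sensor streams handled by the pipeline."""

    HR = "HR"                      # heart rate, bpm (ECG-derived)
    CBT = "CBT"                    # core body temperature, degC
    ACT = "ACT"                    # actigraphy epochs (magnitude, steps)
    GPS = "GPS"                    # waypoints (lat, lon in degrees)
    WBGT_INDOOR = "WBGT_indoor"    # household heat-index logger, degC
    WBGT_OUTDOOR = "WBGT_outdoor"  # weather-station heat index, degC


#: value columns per device in the canonical table format
VALUE_COLUMNS: dict[Device, list[str]] = {
    Device.HR: ["value"],
    Device.CBT: ["value"],
    Device.ACT: ["magnitude", "steps"],
    Device.GPS: ["lat", "lon"],
    Device.WBGT_INDOOR: ["value"],
    Device.WBGT_OUTDOOR: ["value"],
}

UNITS: dict[Device, str] = {
    Device.HR: "bpm",
    Device.CBT: "degC",
    Device.ACT: "g-epoch,steps",
    Device.GPS: "deg",
    Device.WBGT_INDOOR: "degC",
    Device.WBGT_OUTDOOR: "degC",
}

#: devices whose single numeric value supports epoch averaging
AVERAGEABLE = {Device.HR, Device.CBT, Device.WBGT_INDOOR, Device.WBGT_OUTDOOR}

DAY_START = time(6, 30)   # day window [06:30, 18:30), half-open
DAY_END = time(18, 30)


class SchemaError(ValueError):
    """A table is missing required columns."""


class OrderingError(ValueError):
    """Timestamps are not strictly increasing."""


class FormatError(ValueError):
    """A row could not be parsed."""


@dataclass(frozen=True)
class ParticipantProfile:
    """One study participant; couples share a ``household_id``."""

    participant_id: str
    sex: str                      # "female" | "male"
    age: int                      # years
    height_cm: float
    weight_kg: float
    bmi: float                    # kg/m^2
    household_id: str
    fat_mass_pct: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        expected = self.weight_kg / (self.height_cm / 100.0) ** 2
        if abs(expected - self.bmi) > 0.1:
            raise ValueError(
                f"bmi {self.bmi} inconsistent with height/weight ({expected:.2f})"
            )


@dataclass(frozen=True)
class DeviceSpec:
    """Deployment contract for one device kind."""

    device: Device
    intended_hours: float          # denominator of completeness
    nominal_interval_s: float      # coverage credited per sample

    def __post_init__(self) -> None:
        if self.intended_hours <= 0:
            raise ValueError("intended_hours must be positive")
        if self.nominal_interval_s <= 0:
            raise ValueError("nominal_interval_s must be positive")


def device_specs(cfg_devices: dict) -> dict[Device, DeviceSpec]:
    """Build DeviceSpec objects from the ``devices`` config section."""
    out = {}
    for name, hours in cfg_devices["intended_hours"].items():
        dev = Device(name)
        out[dev] = DeviceSpec(dev, float(hours),
                              float(cfg_devices["nominal_interval_s"][name]))
    return out


@dataclass(frozen=True)
class EpochGrid:
    """Fixed averaging grid; epoch label is the epoch *start* time."""

    minutes: int = 5
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.minutes <= 0 or 60 % self.minutes != 0:
            raise ValueError("epoch length must be a positive divisor of 60 minutes")


@dataclass
class SensorSeries:
    """One device's timestamped stream for one participant or household.

    ``data`` holds a ``timestamp`` column (datetime64, strictly increasing)
    plus the device's value columns; missing epochs are absent rows.
    """

    device: Device
    data: pd.DataFrame
    participant_id: str | None = None
    household_id: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            self.units = UNITS[self.device]
        cols = ["timestamp"] + VALUE_COLUMNS[self.device]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"{self.device.value} series missing columns {missing}")
        self.data = self.data.loc[:, cols].reset_index(drop=True)
        ts = self.data["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise OrderingError(f"{self.device.value} timestamps are not increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise OrderingError(f"{self.device.value} timestamps contain duplicates")
        if self.data[VALUE_COLUMNS[self.device]].isna().any().any():
            raise ValueError("sensor series must not contain NaN values (drop the rows)")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def unit_id(self) -> str:
        """Identifier of the wearing unit (participant, or household for WBGT)."""
        return self.participant_id or self.household_id or "?"

    def with_data(self, data: pd.DataFrame) -> "SensorSeries":
        return replace(self, data=data.reset_index(drop=True))

    def values(self) -> np.ndarray:
        """The single numeric value column (averageable devices only)."""
        if self.device not in AVERAGEABLE:
            raise ValueError(f"{self.device.value} has no single value column")
        return self.data["value"].to_numpy()


# ---------------------------------------------------------------------------
# canonical table I/O


def load_sensor_table(path: str | Path, device: Device, *,
                      participant_id: str | None = None,
                      household_id: str | None = None) -> SensorSeries:
    """Read a canonical sensor CSV into a :class:`SensorSeries`.

    Raises :class:`SchemaError` for missing columns, :class:`FormatError`
    (with the offending row index) for unparseable timestamps or values, and
    :class:`OrderingError` for non-monotonic timestamps.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    cols = ["timestamp"] + VALUE_COLUMNS[device]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df.loc[:, cols]
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise FormatError(f"{path}: unparseable timestamp at data row {row}")
    out = {"timestamp": ts}
    for col in VALUE_COLUMNS[device]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"{path}: unparseable {col} at data row {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise FormatError(f"{path}: empty {col} at data row {row}")
        out[col] = vals
    return SensorSeries(device, pd.DataFrame(out),
                        participant_id=participant_id, household_id=household_id)


def write_sensor_table(series: SensorSeries, path: str | Path) -> None:
    """Write the canonical CSV (ISO-8601 seconds, '.' decimals); lossless
    round trip with :func:`load_sensor_table` at stated precision."""
    df = series.data.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# epoch averaging and day/night partition


def epoch_average(series: SensorSeries, grid: EpochGrid = EpochGrid()) -> SensorSeries:
    """Average a numeric series onto the epoch grid.

    Each output sample is the arithmetic mean of the input samples whose
    timestamps fall in ``[epoch_start, epoch_start + grid.minutes)``; epochs
    with no samples are absent rows (gaps are never imputed). Idempotent on
    an already-gridded series.
    """
    if series.device not in AVERAGEABLE:
        raise ValueError(f"epoch averaging unsupported for {series.device.value}")
    if len(series) == 0:
        return series.with_data(series.data)
    df = series.data
    epochs = df["timestamp"].dt.floor(f"{grid.minutes}min")
    agg = df.groupby(epochs)["value"].mean().reset_index()
    return series.with_data(agg)


def _day_mask(timestamps: pd.Series) -> pd.Series:
    tod = timestamps.dt.time
    return (tod >= DAY_START) & (tod < DAY_END)


def day_night_split(series: SensorSeries) -> tuple[SensorSeries, SensorSeries]:
    """Partition samples into day ([06:30, 18:30) local) and night (rest).

    Exhaustive and disjoint: every input sample lands in exactly one half.
    """
    mask = _day_mask(series.data["timestamp"])
    return series.with_data(series.data[mask]), series.with_data(series.data[~mask])


def validate_household_pairs(profiles: Iterable[ParticipantProfile]) -> None:
    """Check the pair structure: exactly one woman and one man per household."""
    by_house: dict[str, list[str]] = {}
    for p in profiles:
        by_house.setdefault(p.household_id, []).append(p.sex)
    for hid, sexes in by_house.items():
        if sorted(sexes) != ["female", "male"]:
            raise ValueError(f"household {hid} must contain one woman and one man")
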