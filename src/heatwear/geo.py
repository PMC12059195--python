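"""Geolocation: Haversine geometry, geofencing and GPS track accounting.

Farm boundaries are circular geofences whose radius is derived from a farm
area in acres (the study design buffers the 1.2-acre average farm to
3 acres to absorb GPS error). Waypoints are labelled home / farm /
elsewhere with home taking precedence over farm where fences overlap.
Track time per label attributes each inter-fix interval to the earlier
fix's label; intervals longer than a gap limit are treated as unobserved.

GPX 1.1 files are read and written with the standard-library XML tools.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088      # IUGG mean Earth radius
SQM_PER_ACRE = 4046.8564224
GPX_NS = "http://www.topografix.com/GPX/1/1"


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float
    timestamp: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class Geofence:
    center: GeoPoint
    radius_m: float
    label: str                    # "home" | "farm"
    area_acres: float | None = None

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("geofence radius must be positive")

    @staticmethod
    def from_area(center: GeoPoint, area_acres: float, label: str) -> "Geofence":
        return Geofence(center, farm_geofence_radius(area_acres), label, area_acres)

    def contains(self, lat: float, lon: float) -> bool:
        return haversine_distance(self.center, GeoPoint(lat, lon)) * 1000.0 <= self.radius_m


def haversine_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on the IUGG mean sphere."""
    return float(_haversine_km(np.array([a.lat]), np.array([a.lon]),
                               np.array([b.lat]), np.array([b.lon]))[0])


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def farm_geofence_radius(area_acres: float) -> float:
    """Radius in metres of the circle with the given area in acres."""
    if area_acres <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(area_acres * SQM_PER_ACRE / math.pi)


def classify_waypoints(track: pd.DataFrame, home: Geofence,
                       farms: list[Geofence]) -> pd.DataFrame:
    """Add a ``label`` column: home > farm > elsewhere precedence."""
    lat = track["lat"].to_numpy()
    lon = track["lon"].to_numpy()
    labels = np.full(len(track), "elsewhere", dtype=object)
    for fence in farms:
        d = _haversine_km(lat, lon,
                          np.full_like(lat, fence.center.lat),
                          np.full_like(lon, fence.center.lon)) * 1000.0
        labels[d <= fence.radius_m] = "farm"
    d_home = _haversine_km(lat, lon,
                           np.full_like(lat, home.center.lat),
                           np.full_like(lon, home.center.lon)) * 1000.0
    labels[d_home <= home.radius_m] = "home"
    out = track.copy()
    out["label"] = labels
    return out


@dataclass(frozen=True)
class TrackSummary:
    distance_km: float
    time_by_label_h: dict[str, float]
    waypoints_by_label: dict[str, int]
    unobserved_h: float = 0.0

    @property
    def duration_h(self) -> float:
        return sum(self.time_by_label_h.values()) + self.unobserved_h


def track_summary(labeled: pd.DataFrame, max_gap_min: float = 10.0) -> TrackSummary:
    """Distance and per-label time accounting of a labelled track.

    Distance is the sum of consecutive Haversine segments. Each inter-fix
    interval is attributed to the earlier fix's label; intervals longer
    than ``max_gap_min`` are counted as unobserved rather than guessed.
    """
    counts = labeled["label"].value_counts().to_dict() if len(labeled) else {}
    if len(labeled) < 2:
        return TrackSummary(0.0, {}, counts)
    lat = labeled["lat"].to_numpy()
    lon = labeled["lon"].to_numpy()
    dist = float(_haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())
    dt_h = labeled["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    observed = dt_h <= max_gap_min / 60.0
    time_by: dict[str, float] = {}
    labels = labeled["label"].to_numpy()[:-1]
    for lab in np.unique(labels):
        time_by[str(lab)] = float(dt_h[(labels == lab) & observed].sum())
    return TrackSummary(dist, time_by, counts,
                        unobserved_h=float(dt_h[~observed].sum()))


# ---------------------------------------------------------------------------
# GPX 1.1 I/O


def write_gpx(track: pd.DataFrame, path: str | Path, creator: str = "heatwear") -> None:
    """Write a track (timestamp, lat, lon) as a one-segment GPX 1.1 file.

    Coordinates keep 7 decimal places (~1 cm), timestamps second precision.
    """
    gpx = ET.Element("gpx", {"version": "1.1", "creator": creator,
                             "xmlns": GPX_NS})
    seg = ET.SubElement(ET.SubElement(gpx, "trk"), "trkseg")
    for row in track.itertuples(index=False):
        pt = ET.SubElement(seg, "trkpt",
                           {"lat": f"{row.lat:.7f}", "lon": f"{row.lon:.7f}"})
        ET.SubElement(pt, "time").text = row.timestamp.strftime("%Y-%m-%dT%H:%M:%S")
    ET.ElementTree(gpx).write(path, encoding="unicode", xml_declaration=True)


def read_gpx(path: str | Path) -> pd.DataFrame:
    """Read all track points of a GPX file into (timestamp, lat, lon).

    Every point must carry a ``<time>`` element — timestamps are required
    for time-in-area accounting.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as err:
        raise ValueError(f"{path}: malformed GPX/XML ({err})") from err
    ns = {"g": GPX_NS}
    rows = []
    for pt in root.findall(".//g:trkpt", ns):
        t = pt.find("g:time", ns)
        if t is None or t.text is None:
            raise ValueError(f"{path}: track point without <time>; timestamps required")
        rows.append({"timestamp": pd.Timestamp(t.text.rstrip("Z")),
                     "lat": float(pt.attrib["lat"]),
                     "lon": float(pt.attrib["lon"])})
    return pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])
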