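"""Readers, writers and core data containers.

All timestamps are UTC epoch seconds internally; ISO-8601 is accepted on
input.  Acceleration is normalised to units of g.  GPS tracks carry WGS84
coordinates and, after :func:`project_track`, planar metres in a local
equirectangular frame about the track centroid (error is negligible at the
few-kilometre scale this pipeline targets, and the projection is exactly
invertible).

Readers validate rather than repair: non-monotone time, non-finite values and
overlapping label intervals are rejected with descriptive errors.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import BehaviourClass, parse_class

#: Mean Earth radius (m); with the equirectangular projection this gives
#: 111.195 m per 0.001 degree of latitude.
EARTH_RADIUS_M = 6_371_008.8

STANDARD_GRAVITY = 9.80665  # m/s^2 per g


class FormatError(ValueError):
    """Raised when an input file violates a format or invariant."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class GapRecord:
    """A hole in a nominally uniform sample stream."""

    start_t: float
    end_t: float
    n_missing: int


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g.

    Attributes
    ----------
    t : ndarray
        Epoch seconds, strictly increasing.
    x, y, z : ndarray
        Acceleration per axis in g (x = surge, y = sway, z = heave).
    rate_hz : float
        Nominal sample rate.
    gaps : list of GapRecord
        Holes longer than two nominal sample intervals, found at read time.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float
    gaps: list[GapRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise FormatError("accel axes and time must have equal length")
        if n == 0:
            raise FormatError("empty accelerometer trace")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise FormatError(
                    f"time not strictly increasing at sample {i + 1}"
                )
            med = float(np.median(dt))
            nominal = 1.0 / self.rate_hz
            if abs(med - nominal) > 0.1 * nominal:
                raise FormatError(
                    f"median sample interval {med:.6g}s deviates >10% from "
                    f"nominal {nominal:.6g}s"
                )
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(a)):
                i = int(np.argmax(~np.isfinite(a)))
                raise FormatError(f"non-finite value on axis {name} at sample {i}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz

    def xyz(self) -> np.ndarray:
        """(n, 3) array of raw triaxial records."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class LabelTrack:
    """Time intervals tagged with behaviour classes.

    Intervals are half-open ``[start, end)``, sorted and non-overlapping.
    """

    intervals: list[tuple[float, float, BehaviourClass]]

    def __post_init__(self) -> None:
        ivals = [(float(s), float(e), c) for s, e, c in self.intervals]
        for s, e, c in ivals:
            if not s < e:
                raise FormatError(f"label interval has start >= end: ({s}, {e}, {c})")
        ivals.sort(key=lambda iv: iv[0])
        bad = [
            (ivals[i], ivals[i + 1])
            for i in range(len(ivals) - 1)
            if ivals[i + 1][0] < ivals[i][1]
        ]
        if bad:
            pairs = "; ".join(f"{a[:2]}/{b[:2]}" for a, b in bad)
            raise FormatError(f"overlapping label intervals: {pairs}")
        self.intervals = ivals

    def __len__(self) -> int:
        return len(self.intervals)

    def sample_classes(
        self, t: np.ndarray, default: BehaviourClass = BehaviourClass.OTHER
    ) -> np.ndarray:
        """Class of each timestamp in ``t`` (object array of BehaviourClass).

        Times not covered by any interval get ``default``.
        """
        t = np.asarray(t, dtype=float)
        out = np.full(len(t), default, dtype=object)
        if not self.intervals:
            return out
        starts = np.array([iv[0] for iv in self.intervals])
        ends = np.array([iv[1] for iv in self.intervals])
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
        cls_arr = np.array([iv[2] for iv in self.intervals], dtype=object)
        out[ok] = cls_arr[idx[ok]]
        return out

    def scent_intervals(self) -> list[tuple[float, float, BehaviourClass]]:
        return [iv for iv in self.intervals if iv[2] != BehaviourClass.OTHER]


@dataclass
class GpsTrack:
    """GPS fixes in WGS84, optionally with a local planar frame in metres."""

    t: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    x_m: np.ndarray | None = None
    y_m: np.ndarray | None = None
    origin: tuple[float, float] | None = None  # (lon0, lat0) of planar frame

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.t) == len(self.lon) == len(self.lat)):
            raise FormatError("GPS fields must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0))
            raise FormatError(f"GPS time not strictly increasing at fix {i + 1}")
        if np.any((self.lat < -90) | (self.lat > 90)):
            raise FormatError("latitude outside [-90, 90]")
        if np.any((self.lon < -180) | (self.lon > 180)):
            raise FormatError("longitude outside [-180, 180]")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def projected(self) -> bool:
        return self.x_m is not None

    def xy(self) -> np.ndarray:
        if not self.projected:
            raise ValueError("track not projected; call project_track first")
        return np.column_stack([self.x_m, self.y_m])


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def wgs84_to_planar(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection about ``origin=(lon0, lat0)``."""
    lon0, lat0 = origin
    k = math.pi / 180.0 * EARTH_RADIUS_M
    x = (np.asarray(lon, float) - lon0) * k * math.cos(math.radians(lat0))
    y = (np.asarray(lat, float) - lat0) * k
    return x, y


def planar_to_wgs84(
    x: np.ndarray, y: np.ndarray, origin: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`wgs84_to_planar`."""
    lon0, lat0 = origin
    k = math.pi / 180.0 * EARTH_RADIUS_M
    lon = np.asarray(x, float) / (k * math.cos(math.radians(lat0))) + lon0
    lat = np.asarray(y, float) / k + lat0
    return lon, lat


def project_track(track: GpsTrack) -> GpsTrack:
    """Return a copy of ``track`` with planar metres about its centroid."""
    if len(track) == 0:
        raise FormatError("cannot project an empty track")
    origin = (float(np.mean(track.lon)), float(np.mean(track.lat)))
    x, y = wgs84_to_planar(track.lon, track.lat, origin)
    return GpsTrack(
        t=track.t.copy(),
        lon=track.lon.copy(),
        lat=track.lat.copy(),
        x_m=x,
        y_m=y,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# Time parsing
# ---------------------------------------------------------------------------


def _parse_time(value: str) -> float:
    """Epoch seconds from an epoch number or ISO-8601 string (UTC default)."""
    s = str(value).strip()
    try:
        return float(s)
    except ValueError:
        pass
    iso = s.replace("Z", "+00:00")
    dt = datetime.fromisoformat(iso)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _iso(t: float) -> str:
    return (
        datetime.fromtimestamp(t, tz=timezone.utc)
        .isoformat()
        .replace("+00:00", "Z")
    )


def _pick_column(columns: Sequence[str], candidates: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise FormatError(
        f"missing {what} column (looked for {list(candidates)}; "
        f"found {list(columns)})"
    )


# ---------------------------------------------------------------------------
# Accelerometer CSV
# ---------------------------------------------------------------------------


def read_accel_csv(
    path: str | Path,
    rate_hz: float = 50.0,
    units: str = "g",
    clock_offset_s: float = 0.0,
) -> AccelTrace:
    """Read an accelerometer CSV into an :class:`AccelTrace`.

    Parameters
    ----------
    units : {"g", "m/s2"}
        Input acceleration units; "m/s2" values are divided by 9.80665.
    clock_offset_s :
        Constant added to every timestamp (accel/GPS clock alignment).

    Gaps longer than two nominal sample intervals are recorded on
    ``trace.gaps`` (the data is not resampled).
    """
    if units not in ("g", "m/s2"):
        raise ValueError(f"units must be 'g' or 'm/s2', got {units!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    tcol = _pick_column(df.columns, ("epoch_s", "t", "time", "timestamp"), "time")
    xcol = _pick_column(df.columns, ("x_g", "x", "ax"), "x axis")
    ycol = _pick_column(df.columns, ("y_g", "y", "ay"), "y axis")
    zcol = _pick_column(df.columns, ("z_g", "z", "az"), "z axis")
    try:
        t = df[tcol].map(_parse_time).to_numpy(dtype=float)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse time column: {exc}") from exc
    t = t + clock_offset_s
    axes = df[[xcol, ycol, zcol]].to_numpy(dtype=float)
    for j, name in enumerate("xyz"):
        bad = ~np.isfinite(axes[:, j])
        if bad.any():
            line = int(np.argmax(bad)) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-finite {name} value at line {line}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise FormatError(f"{path}: time not strictly increasing at line {line}")
    if units == "m/s2":
        axes = axes / STANDARD_GRAVITY
    nominal = 1.0 / rate_hz
    gaps: list[GapRecord] = []
    for i in np.nonzero(dt > 2 * nominal)[0]:
        missing = int(round(dt[i] / nominal)) - 1
        gaps.append(GapRecord(float(t[i]), float(t[i + 1]), missing))
    trace = AccelTrace(
        t=t, x=axes[:, 0], y=axes[:, 1], z=axes[:, 2], rate_hz=rate_hz
    )
    trace.gaps = gaps
    return trace


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"epoch_s": trace.t, "x_g": trace.x, "y_g": trace.y, "z_g": trace.z}
    )
    # shortest-repr floats: exact round trip through read_accel_csv
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Label CSV
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> LabelTrack:
    """Read an annotation CSV of (start_s, end_s, class) intervals."""
    df = pd.read_csv(path)
    scol = _pick_column(df.columns, ("start_s", "start", "begin"), "start")
    ecol = _pick_column(df.columns, ("end_s", "end", "stop"), "end")
    ccol = _pick_column(df.columns, ("class", "label", "behaviour", "behavior"), "class")
    intervals = [
        (float(r[scol]), float(r[ecol]), parse_class(str(r[ccol])))
        for _, r in df.iterrows()
    ]
    return LabelTrack(intervals)


def write_labels(labels: LabelTrack, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "class"])
        for s, e, c in labels.intervals:
            w.writerow([f"{s:.17g}", f"{e:.17g}", c.value])


# ---------------------------------------------------------------------------
# GPS: CSV and GPX 1.1
# ---------------------------------------------------------------------------

_GPX_NS = "http://www.topografix.com/GPX/1/1"


def read_gps(path: str | Path, clock_offset_s: float = 0.0) -> GpsTrack:
    """Read a GPS track from CSV or GPX (dispatch on file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        return _read_gpx(path, clock_offset_s)
    df = pd.read_csv(path, float_precision="round_trip")
    tcol = _pick_column(df.columns, ("time", "timestamp", "t", "epoch_s"), "time")
    latcol = _pick_column(df.columns, ("lat", "latitude"), "latitude")
    loncol = _pick_column(df.columns, ("lon", "lng", "longitude"), "longitude")
    t = df[tcol].map(_parse_time).to_numpy(dtype=float) + clock_offset_s
    return GpsTrack(
        t=t,
        lon=df[loncol].to_numpy(dtype=float),
        lat=df[latcol].to_numpy(dtype=float),
    )


def _read_gpx(path: Path, clock_offset_s: float) -> GpsTrack:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed GPX: {exc}") from exc
    ts, lons, lats = [], [], []
    for el in root.iter():
        if el.tag.rsplit("}", 1)[-1] != "trkpt":
            continue
        try:
            lats.append(float(el.attrib["lat"]))
            lons.append(float(el.attrib["lon"]))
        except KeyError as exc:
            raise FormatError(f"{path}: trkpt missing lat/lon") from exc
        tval = None
        for child in el:
            if child.tag.rsplit("}", 1)[-1] == "time":
                tval = _parse_time(child.text or "")
        if tval is None:
            raise FormatError(f"{path}: trkpt without <time>")
        ts.append(tval + clock_offset_s)
    if not ts:
        raise FormatError(f"{path}: no trackpoints found")
    return GpsTrack(t=np.array(ts), lon=np.array(lons), lat=np.array(lats))


def write_gps_csv(track: GpsTrack, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "lat", "lon"])
        for t, lat, lon in zip(track.t, track.lat, track.lon):
            w.writerow([_iso(t), f"{lat:.17g}", f"{lon:.17g}"])


def write_gpx(track: GpsTrack, path: str | Path, name: str = "track") -> None:
    ET.register_namespace("", _GPX_NS)
    gpx = ET.Element(f"{{{_GPX_NS}}}gpx", version="1.1", creator="scentmark")
    trk = ET.SubElement(gpx, f"{{{_GPX_NS}}}trk")
    ET.SubElement(trk, f"{{{_GPX_NS}}}name").text = name
    seg = ET.SubElement(trk, f"{{{_GPX_NS}}}trkseg")
    for t, lat, lon in zip(track.t, track.lat, track.lon):
        pt = ET.SubElement(
            seg, f"{{{_GPX_NS}}}trkpt", lat=f"{lat:.17g}", lon=f"{lon:.17g}"
        )
        ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = _iso(t)
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Predictions and GeoJSON
# ---------------------------------------------------------------------------


def write_predictions_csv(
    t: Iterable[float], labels: Iterable[BehaviourClass], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "class"])
        for ti, ci in zip(t, labels):
            w.writerow([f"{float(ti):.17g}", BehaviourClass(ci).value])


def read_predictions_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    labels = np.array([parse_class(c) for c in df["class"]], dtype=object)
    return t, labels


def write_events_geojson(events, path: str | Path) -> None:
    """Write scent-mark events as a GeoJSON FeatureCollection of points.

    Unlocated events are emitted with null geometry and ``located: false``.
    """
    feats = []
    for ev in events:
        geom = None
        if ev.lon is not None and ev.lat is not None:
            geom = {"type": "Point", "coordinates": [ev.lon, ev.lat]}
        feats.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "class": ev.cls.value,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "located": geom is not None,
                    "source_fix_t": ev.source_fix_t,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {"crs": "WGS84", "planar_frame": "local equirectangular"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def write_polygon_geojson(
    ring_lonlat: np.ndarray, path: str | Path, properties: dict | None = None
) -> None:
    coords = [[float(a), float(b)] for a, b in ring_lonlat]
    if coords and coords[0] != coords[-1]:
        coords.append(coords[0])
    doc = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [coords]},
        "properties": properties or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
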