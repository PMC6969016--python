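"""Synthetic labelled accelerometer traces and GPS tracks.

The generative model mirrors what a pelvis-mounted tri-axial accelerometer
sees: held scent-marking postures are quasi-static gravity projections
(left-leg tilts the sway axis to about -1 g, right-leg to +1 g, squats tilt
the surge axis to about -1 g), embedded in dynamic "other" behaviour modelled
as a zero-mean sinusoid plus Gaussian noise around the baseline standing
orientation (z = -1 g, x = y = 0).  Posture onsets are instantaneous.

GPS fixes come from a mean-reverting random walk confined to a territory
disc, with occasional forays during which the walk's attractor is displaced
outside the territory.  The walk is clamped strictly inside the disc outside
forays and strictly outside during them, so ground-truth foray windows are
exactly the spans of outside fixes.

Everything is driven by a single seed; repeated calls with the same config
produce byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .classes import BehaviourClass
from .io import AccelTrace, GpsTrack, LabelTrack, planar_to_wgs84


@dataclass
class SimConfig:
    """Parameters of the simulator; see module docstring for the model."""

    seed: int = 0
    duration_s: float = 3600.0
    accel_rate_hz: float = 50.0
    gps_interval_s: float = 5.0
    noise_sd_g: float = 0.1
    posture_hold_s: tuple[float, float] = (2.0, 5.0)
    marks_per_hour: float = 4.0  # per scent class
    territory_radius_m: float = 200.0
    foray_prob_per_min: float = 0.02
    foray_mean_duration_s: float = 300.0
    sex: str = "male"
    # secondary knobs
    t0: float = 0.0
    other_dynamic_amp_g: float = 0.25
    squat_defaecate_offset_g: float = 0.08
    include_defaecation: bool = True
    mount_roll_deg: float = 0.0  # per-individual device mounting offset
    walk_speed_mps: float = 1.0
    gps_jitter_sd_m: float = 5.0
    anchor_lon: float = -123.083
    anchor_lat: float = 39.0

    def __post_init__(self) -> None:
        if self.accel_rate_hz <= 0:
            raise ValueError("accel_rate_hz must be > 0")
        if self.gps_interval_s <= 0:
            raise ValueError("gps_interval_s must be > 0")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if not 0.0 <= self.foray_prob_per_min <= 1.0:
            raise ValueError("foray_prob_per_min must be in [0, 1]")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        lo, hi = self.posture_hold_s
        if not 0 < lo <= hi:
            raise ValueError("posture_hold_s must be a positive (lo, hi) range")

    def scent_classes(self) -> list[BehaviourClass]:
        if self.sex == "male":
            return [BehaviourClass.LEFT_LEG, BehaviourClass.RIGHT_LEG]
        classes = [BehaviourClass.SQUAT_URINATE]
        if self.include_defaecation:
            classes.append(BehaviourClass.SQUAT_DEFAECATE)
        return classes


@dataclass
class GroundTruth:
    """What the simulator actually did, for downstream validation."""

    label_track: LabelTrack
    #: (time_s, x_m, y_m, class) per scent mark; planar coords in the anchor
    #: frame, NaN until simulate_gps has run.
    mark_locations: list[tuple[float, float, float, BehaviourClass]] = field(
        default_factory=list
    )
    #: (start_s, end_s) spans of fixes outside the territory.
    foray_windows: list[tuple[float, float]] = field(default_factory=list)


class SimResult(NamedTuple):
    trace: AccelTrace
    labels: LabelTrack
    track: GpsTrack
    truth: GroundTruth


def _gravity_vector(cls: BehaviourClass, cfg: SimConfig) -> np.ndarray:
    if cls == BehaviourClass.LEFT_LEG:
        g = [0.0, -1.0, 0.0]
    elif cls == BehaviourClass.RIGHT_LEG:
        g = [0.0, 1.0, 0.0]
    elif cls == BehaviourClass.SQUAT_URINATE:
        g = [-1.0, 0.0, 0.0]
    elif cls == BehaviourClass.SQUAT_DEFAECATE:
        g = [-1.0 + cfg.squat_defaecate_offset_g, 0.0, 0.0]
    else:  # baseline standing orientation
        g = [0.0, 0.0, -1.0]
    v = np.array(g)
    if cfg.mount_roll_deg:
        a = math.radians(cfg.mount_roll_deg)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(a), -math.sin(a)],
                [0.0, math.sin(a), math.cos(a)],
            ]
        )
        v = rot @ v
    return v


def _draw_events(
    cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float, BehaviourClass]]:
    """Poisson event times per class, thinned to avoid overlap."""
    lo, hi = cfg.posture_hold_s
    hours = cfg.duration_s / 3600.0
    if cfg.duration_s < 2 * hi:
        raise ValueError(
            f"duration_s={cfg.duration_s} too short to place posture events "
            f"of up to {hi}s"
        )
    classes = cfg.scent_classes()
    expected_busy = cfg.marks_per_hour * hours * hi * len(classes)
    if expected_busy > 0.5 * cfg.duration_s:
        raise ValueError(
            "duration too short for the requested event rate: expected "
            f"{expected_busy:.0f}s of postures in {cfg.duration_s:.0f}s"
        )
    candidates: list[tuple[float, float, BehaviourClass]] = []
    for cls in classes:
        n = rng.poisson(cfg.marks_per_hour * hours)
        starts = rng.uniform(0.0, cfg.duration_s - hi, size=n)
        holds = rng.uniform(lo, hi, size=n)
        candidates.extend((float(s), float(h), cls) for s, h in zip(starts, holds))
    candidates.sort(key=lambda e: e[0])
    events: list[tuple[float, float, BehaviourClass]] = []
    guard = 1.0  # min spacing between consecutive postures (s)
    t_free = 0.0
    for s, h, cls in candidates:
        if s >= t_free:
            events.append((s, s + h, cls))
            t_free = s + h + guard
    return events


def simulate_accel(cfg: SimConfig) -> tuple[AccelTrace, LabelTrack]:
    """Generate a labelled accelerometer trace.

    Returns the trace and a label track that covers the full duration
    (scent intervals plus OTHER intervals in between).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n = int(round(cfg.duration_s * cfg.accel_rate_hz))
    t = cfg.t0 + np.arange(n) / cfg.accel_rate_hz
    rel = np.arange(n) / cfg.accel_rate_hz

    base = _gravity_vector(BehaviourClass.OTHER, cfg)
    sig = np.tile(base, (n, 1))

    events = _draw_events(cfg, rng)

    # Dynamic "other" behaviour: piecewise sinusoid bouts + Gaussian noise.
    # The sinusoid is a stand-in for locomotion; its amplitude is a knob, not
    # a biomechanical claim.
    amp = cfg.other_dynamic_amp_g
    if amp > 0:
        bout_edges = [0.0]
        while bout_edges[-1] < cfg.duration_s:
            bout_edges.append(bout_edges[-1] + float(rng.uniform(5.0, 30.0)))
        for b0, b1 in zip(bout_edges[:-1], bout_edges[1:]):
            i0, i1 = np.searchsorted(rel, [b0, b1])
            if i1 <= i0:
                continue
            freq = rng.uniform(1.5, 3.5)
            for axis in range(3):
                a = amp * rng.uniform(0.5, 1.0)
                phase = rng.uniform(0.0, 2 * math.pi)
                sig[i0:i1, axis] += a * np.sin(
                    2 * math.pi * freq * rel[i0:i1] + phase
                )

    # Postures override the dynamic signal (instantaneous orientation change).
    intervals: list[tuple[float, float, BehaviourClass]] = []
    cursor = 0.0
    for s, e, cls in events:
        if s > cursor:
            intervals.append(
                (cfg.t0 + cursor, cfg.t0 + s, BehaviourClass.OTHER)
            )
        i0, i1 = np.searchsorted(rel, [s, e])
        sig[i0:i1] = _gravity_vector(cls, cfg)
        intervals.append((cfg.t0 + s, cfg.t0 + e, cls))
        cursor = e
    if cursor < cfg.duration_s:
        intervals.append(
            (cfg.t0 + cursor, cfg.t0 + cfg.duration_s, BehaviourClass.OTHER)
        )

    if cfg.noise_sd_g > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd_g, size=sig.shape)

    trace = AccelTrace(
        t=t, x=sig[:, 0], y=sig[:, 1], z=sig[:, 2], rate_hz=cfg.accel_rate_hz
    )
    return trace, LabelTrack(intervals)


def _draw_foray_plan(
    cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Intended foray windows (continuous time), non-overlapping."""
    plan: list[tuple[float, float]] = []
    minute = 0
    min_dur = 3.0 * cfg.gps_interval_s
    while minute * 60.0 < cfg.duration_s:
        t_min = minute * 60.0
        if plan and t_min < plan[-1][1]:
            minute += 1
            continue
        if rng.uniform() < cfg.foray_prob_per_min:
            start = t_min + float(rng.uniform(0.0, 60.0))
            dur = max(min_dur, float(rng.exponential(cfg.foray_mean_duration_s)))
            end = min(start + dur, cfg.duration_s - cfg.gps_interval_s)
            if end - start >= min_dur:
                plan.append((start, end))
        minute += 1
    return plan


def simulate_gps(cfg: SimConfig, truth: GroundTruth) -> GpsTrack:
    """Generate a GPS track consistent with ``truth``'s label timeline.

    Fills ``truth.mark_locations`` with the (noise-free) walk position at
    each scent-mark onset and ``truth.foray_windows`` with the realised
    outside-fix spans.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    dt = cfg.gps_interval_s
    n_fix = int(math.floor(cfg.duration_s / dt)) + 1
    rel = np.arange(n_fix) * dt

    plan = _draw_foray_plan(cfg, rng)
    in_foray = np.zeros(n_fix, dtype=bool)
    foray_dir: dict[int, np.ndarray] = {}
    for k, (s, e) in enumerate(plan):
        mask = (rel >= s) & (rel < e)
        in_foray |= mask
        ang = rng.uniform(0.0, 2 * math.pi)
        for i in np.nonzero(mask)[0]:
            foray_dir[i] = np.array([math.cos(ang), math.sin(ang)])

    R = cfg.territory_radius_m
    theta = 0.005  # mean-reversion rate, 1/s
    step_sd = cfg.walk_speed_mps * dt / math.sqrt(2.0)
    pos = np.zeros((n_fix, 2))
    p = np.zeros(2)
    steps = rng.normal(0.0, step_sd, size=(n_fix, 2))
    for i in range(n_fix):
        if in_foray[i]:
            attractor = foray_dir[i] * 1.6 * R
        else:
            attractor = np.zeros(2)
        p = p + theta * dt * (attractor - p) + steps[i]
        r = float(np.hypot(*p))
        if in_foray[i]:
            if r < 1.05 * R:
                d = foray_dir[i] if r == 0.0 else p / r
                p = d * 1.05 * R
        else:
            if r > 0.95 * R:
                p = p * (0.95 * R / r)
        pos[i] = p

    # realised foray windows = contiguous runs of outside fixes
    outside = np.hypot(pos[:, 0], pos[:, 1]) > R
    truth.foray_windows = []
    i = 0
    while i < n_fix:
        if outside[i]:
            j = i
            while j + 1 < n_fix and outside[j + 1]:
                j += 1
            truth.foray_windows.append(
                (cfg.t0 + float(rel[i]), cfg.t0 + float(rel[j]))
            )
            i = j + 1
        else:
            i += 1

    # scent-mark locations: walk position interpolated at posture onset
    truth.mark_locations = []
    for s, _e, cls in truth.label_track.scent_intervals():
        xs = float(np.interp(s - cfg.t0, rel, pos[:, 0]))
        ys = float(np.interp(s - cfg.t0, rel, pos[:, 1]))
        truth.mark_locations.append((s, xs, ys, cls))

    fixes = pos.copy()
    if cfg.gps_jitter_sd_m > 0:
        fixes = fixes + rng.normal(0.0, cfg.gps_jitter_sd_m, size=fixes.shape)
    lon, lat = planar_to_wgs84(
        fixes[:, 0], fixes[:, 1], (cfg.anchor_lon, cfg.anchor_lat)
    )
    return GpsTrack(t=cfg.t0 + rel, lon=lon, lat=lat)


def simulate(cfg: SimConfig) -> SimResult:
    """Full simulation: accelerometer trace, labels, GPS track, ground truth."""
    trace, labels = simulate_accel(cfg)
    truth = GroundTruth(label_track=labels)
    track = simulate_gps(cfg, truth)
    return SimResult(trace, labels, track, truth)


def write_truth_geojson(truth: GroundTruth, cfg: SimConfig, path) -> None:
    """Ground-truth mark points and foray windows as GeoJSON."""
    feats = []
    for t, x, y, cls in truth.mark_locations:
        lon, lat = planar_to_wgs84(
            np.array([x]), np.array([y]), (cfg.anchor_lon, cfg.anchor_lat)
        )
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(lon[0]), float(lat[0])],
                },
                "properties": {"t": t, "class": cls.value, "x_m": x, "y_m": y},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {
            "foray_windows": [[s, e] for s, e in truth.foray_windows],
            "anchor": [cfg.anchor_lon, cfg.anchor_lat],
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
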