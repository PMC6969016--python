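"""End-to-end orchestration: simulate / validate / deploy runs.

A run is driven by a flat config mapping (YAML or dict), executes its stages
in order, writes every intermediate artefact into the output directory, and
finishes with a ``manifest.json`` recording the seed, parameters, per-stage
record counts and a SHA-256 digest of every output file.  Identical config
and seed give byte-identical outputs.

Modes mirror the two experiments the method supports:

* ``validate`` — accelerometer + full annotations -> classifier metrics;
* ``deploy``   — accelerometer + annotation window (+ GPS) -> 1 Hz series,
  scent-mark events, and the spatial indices (home range, territory,
  overlap, revisits, forays).  Without GPS the spatial stages are skipped
  and flagged.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .classes import BehaviourClass
from .classifier import (
    DEFAULT_K_GRID,
    KnnClassifier,
    build_testing_set,
    build_training_set,
    evaluate,
    tune_k,
)
from .io import (
    AccelTrace,
    GpsTrack,
    LabelTrack,
    planar_to_wgs84,
    project_track,
    read_accel_csv,
    read_gps,
    read_labels,
    write_accel_csv,
    write_events_geojson,
    write_gps_csv,
    write_labels,
    write_polygon_geojson,
    write_predictions_csv,
)
from .postprocess import (
    extract_events,
    georeference,
    marking_rate,
    smooth_modal,
)
from .spatial import (
    detect_forays,
    detect_revisits,
    mcp,
    mean_revisit_interval_h,
    overlap_proportion,
)
from .synthetic import SimConfig, simulate, write_truth_geojson


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat run configuration (all keys optional except mode-specific paths)."""

    mode: str = "deploy"  # simulate | validate | deploy
    seed: int = 0
    out_dir: str = "run"
    # inputs
    accel_csv: str | None = None
    labels_csv: str | None = None
    gps_path: str | None = None
    rate_hz: float = 50.0
    clock_offset_s: float = 0.0
    # simulation (also used when accel_csv is absent in validate/deploy)
    duration_s: float = 3600.0
    sex: str = "male"
    marks_per_hour: float = 4.0
    noise_sd_g: float = 0.1
    gps_jitter_sd_m: float = 5.0
    territory_radius_m: float = 200.0
    foray_prob_per_min: float = 0.02
    # classifier
    n_scent: int = 50
    n_other: int = 500
    n_other_test: int = 3000
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    folds: int = 5
    vote: str = "majority"
    # smoothing / events
    min_duration_s: float = 2.0
    georef_tolerance_s: float = 10.0
    obs_window_s: float = 3600.0
    # spatial
    mcp_percent: float = 95.0
    buffer_m: float = 10.0
    split_min: float = 10.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("simulate", "validate", "deploy"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if isinstance(cfg.k_grid, list):
            cfg.k_grid = tuple(int(k) for k in cfg.k_grid)
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=self.seed,
            duration_s=self.duration_s,
            accel_rate_hz=self.rate_hz,
            sex=self.sex,
            marks_per_hour=self.marks_per_hour,
            noise_sd_g=self.noise_sd_g,
            gps_jitter_sd_m=self.gps_jitter_sd_m,
            territory_radius_m=self.territory_radius_m,
            foray_prob_per_min=self.foray_prob_per_min,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _load_inputs(
    cfg: RunConfig, outdir: Path, manifest: dict
) -> tuple[AccelTrace, LabelTrack, GpsTrack | None]:
    """Read configured inputs, simulating any that are missing."""
    need_sim = cfg.accel_csv is None or (
        cfg.mode == "deploy" and cfg.gps_path is None and cfg.labels_csv is None
    )
    sim = None
    if cfg.accel_csv is None:
        sim = simulate(cfg.sim_config())
        write_accel_csv(sim.trace, outdir / "accel.csv")
        write_labels(sim.labels, outdir / "labels.csv")
        write_gps_csv(sim.track, outdir / "gps.csv")
        write_truth_geojson(sim.truth, cfg.sim_config(), outdir / "truth.geojson")
        manifest["stages"]["simulate"] = {
            "n_samples": len(sim.trace),
            "n_label_intervals": len(sim.labels),
            "n_fixes": len(sim.track),
        }
        trace, labels = sim.trace, sim.labels
        gps = sim.track if cfg.mode == "deploy" else None
        return trace, labels, gps
    trace = read_accel_csv(
        cfg.accel_csv, rate_hz=cfg.rate_hz, clock_offset_s=cfg.clock_offset_s
    )
    if cfg.labels_csv is None:
        raise ValueError("labels_csv is required when accel_csv is given")
    labels = read_labels(cfg.labels_csv)
    gps = None
    if cfg.gps_path is not None:
        gps = read_gps(cfg.gps_path)
    return trace, labels, gps


def run_pipeline(config: RunConfig | dict, outdir: str | Path) -> dict:
    """Execute a full run; returns (and writes) the manifest."""
    cfg = (
        config
        if isinstance(config, RunConfig)
        else RunConfig.from_dict(dict(config))
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "stages": {},
        "skipped": [],
        "outputs": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("inputs"):
        trace, labels, gps = _load_inputs(cfg, outdir, manifest)

    if cfg.mode == "simulate":
        _finalise(manifest, outdir)
        return manifest

    with stage("train"):
        if cfg.mode == "deploy":
            t_lo = float(trace.t[0])
            window = [
                iv
                for iv in labels.intervals
                if iv[0] < t_lo + cfg.obs_window_s
            ]
            train_labels = LabelTrack(window)
        else:
            train_labels = labels
        training = build_training_set(
            trace,
            train_labels,
            n_scent=cfg.n_scent,
            n_other=cfg.n_other,
            seed=cfg.seed,
        )
        k_best, cv_table = tune_k(
            trace,
            train_labels,
            k_grid=cfg.k_grid,
            folds=cfg.folds,
            seed=cfg.seed,
            training=training,
            vote=cfg.vote,
        )
        model = KnnClassifier(training=training, k=k_best, vote=cfg.vote)
        model.to_json(outdir / "model.json")
        _write_csv(
            outdir / "cv_table.csv",
            ["k", "mean_accuracy"],
            [[r["k"], f"{r['mean_accuracy']:.6f}"] for r in cv_table],
        )
        manifest["stages"]["train"] = {
            "n_training": len(training),
            "k_best": k_best,
        }

    if cfg.mode == "validate":
        with stage("evaluate"):
            testing = build_testing_set(
                trace,
                train_labels,
                training,
                n_other_test=cfg.n_other_test,
                seed=cfg.seed,
            )
            pred, scores = model.predict_scores(testing.records)
            report = evaluate(testing.labels, pred, scores=scores)
            report.to_json(outdir / "metrics.json")
            manifest["stages"]["evaluate"] = {
                "n_test": len(testing),
                "accuracy": report.accuracy,
                "weighted_f1": report.weighted_f1,
            }
        _finalise(manifest, outdir)
        return manifest

    # deploy mode ----------------------------------------------------------
    with stage("predict"):
        pred = model.predict(trace.xyz())
        manifest["stages"]["predict"] = {"n_samples": len(pred)}

    with stage("smooth"):
        series = smooth_modal(pred, trace.t, rate_hz=trace.rate_hz)
        write_predictions_csv(
            series.times(), series.classes(), outdir / "series_1hz.csv"
        )
        manifest["stages"]["smooth"] = {"n_bins": len(series)}

    with stage("events"):
        events = extract_events(series, min_duration_s=cfg.min_duration_s)
        manifest["stages"]["events"] = {"n_events": len(events)}

    located = events
    if gps is None:
        manifest["skipped"].append("georef")
        manifest["skipped"].extend(
            ["homerange", "territory", "overlap", "revisits", "forays"]
        )
    else:
        with stage("georef"):
            gps = project_track(gps)
            located = georeference(
                events, gps, tolerance_s=cfg.georef_tolerance_s
            )
            manifest["stages"]["georef"] = {
                "n_located": sum(e.located for e in located)
            }
    _write_events(located, outdir)

    summary: dict = {
        "n_scent_marks": len(events),
        "deployment_hours": (
            (float(trace.t[-1]) - float(trace.t[0])) / 3600.0
        ),
    }
    summary["marks_per_hour"] = (
        marking_rate(len(events), summary["deployment_hours"])
        if summary["deployment_hours"] > 0
        else None
    )

    if gps is not None:
        with stage("spatial"):
            _spatial_stages(cfg, gps, located, outdir, manifest, summary)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _finalise(manifest, outdir)
    return manifest


def _write_events(events, outdir: Path) -> None:
    rows = []
    for e in events:
        rows.append(
            [
                f"{e.start_s:.17g}",
                f"{e.end_s:.17g}",
                e.cls.value,
                int(e.located),
                "" if e.x_m is None else f"{e.x_m:.6f}",
                "" if e.y_m is None else f"{e.y_m:.6f}",
                "" if e.lon is None else f"{e.lon:.10f}",
                "" if e.lat is None else f"{e.lat:.10f}",
                "" if e.source_fix_t is None else f"{e.source_fix_t:.17g}",
            ]
        )
    _write_csv(
        outdir / "events.csv",
        ["start_s", "end_s", "class", "located", "x_m", "y_m", "lon", "lat",
         "source_fix_t"],
        rows,
    )
    write_events_geojson(events, outdir / "events.geojson")


def _spatial_stages(cfg, gps, located, outdir, manifest, summary) -> None:
    homerange = mcp(gps.xy(), percent=cfg.mcp_percent)
    ring = homerange.ring()
    lon, lat = planar_to_wgs84(ring[:, 0], ring[:, 1], gps.origin)
    write_polygon_geojson(
        np.column_stack([lon, lat]),
        outdir / "homerange.geojson",
        {"kind": "homerange", "percent": cfg.mcp_percent,
         "area_m2": homerange.area_m2,
         "projection": "local equirectangular about track centroid"},
    )
    summary["homerange_area_m2"] = homerange.area_m2
    manifest["stages"]["homerange"] = {"n_fixes": homerange.n_points_total}

    mark_pts = np.array([[e.x_m, e.y_m] for e in located if e.located])
    territory = None
    if len(mark_pts) >= 3:
        try:
            territory = mcp(mark_pts, percent=cfg.mcp_percent)
        except ValueError:
            manifest["skipped"].append("territory")
    else:
        manifest["skipped"].append("territory")
    if territory is not None:
        ring = territory.ring()
        lon, lat = planar_to_wgs84(ring[:, 0], ring[:, 1], gps.origin)
        write_polygon_geojson(
            np.column_stack([lon, lat]),
            outdir / "territory.geojson",
            {"kind": "territory", "percent": cfg.mcp_percent,
             "area_m2": territory.area_m2,
             "projection": "local equirectangular about track centroid"},
        )
        summary["territory_area_m2"] = territory.area_m2
        summary["overlap_proportion"] = overlap_proportion(homerange, territory)
        manifest["stages"]["territory"] = {"n_marks": len(mark_pts)}

        forays, fsummary = detect_forays(gps, territory, split_min=cfg.split_min)
        _write_csv(
            outdir / "forays.csv",
            ["start_t", "end_t", "duration_min", "n_fixes",
             "max_displacement_m"],
            [
                [f"{f.start_t:.17g}", f"{f.end_t:.17g}",
                 f"{f.duration_min:.6f}", f.n_fixes,
                 f"{f.max_displacement_m:.3f}"]
                for f in forays
            ],
        )
        summary["forays"] = fsummary.to_dict()
        manifest["stages"]["forays"] = {"n_forays": len(forays)}

    revisits = detect_revisits(located, buffer_m=cfg.buffer_m)
    _write_csv(
        outdir / "revisits.csv",
        ["earlier_start_s", "later_start_s", "distance_m", "interval_h"],
        [
            [f"{r.earlier.start_s:.17g}", f"{r.later.start_s:.17g}",
             f"{r.distance_m:.3f}", f"{r.interval_h:.6f}"]
            for r in revisits
        ],
    )
    summary["n_revisits"] = len(revisits)
    summary["mean_revisit_interval_h"] = mean_revisit_interval_h(revisits)
    manifest["stages"]["revisits"] = {"n_revisits": len(revisits)}


def _finalise(manifest: dict, outdir: Path) -> None:
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or not p.is_file():
            continue
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
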