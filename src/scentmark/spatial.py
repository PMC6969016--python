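"""Spatial indices: MCP home range / territory, overlap, revisits, forays.

The percent MCP follows the standard home-range convention: discard the
fraction of points farthest from the arithmetic centroid, then take the
convex hull of the remainder.  Territory is the MCP over scent-mark locations
only; excursions from it are extra-territorial forays, timed from the first
fix outside to the last fix before re-entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon

from .io import GpsTrack
from .postprocess import ScentMarkEvent


@dataclass
class McpResult:
    """A percent minimum convex polygon over planar points."""

    polygon: Polygon
    area_m2: float
    percent: float
    n_points_in: int
    n_points_total: int

    def ring(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)


@dataclass
class Foray:
    """One maximal run of fixes outside the territory polygon."""

    start_t: float
    end_t: float
    n_fixes: int
    max_displacement_m: float

    @property
    def duration_min(self) -> float:
        return (self.end_t - self.start_t) / 60.0


@dataclass
class RevisitEvent:
    """A scent mark placed within the buffer of an earlier mark."""

    earlier: ScentMarkEvent
    later: ScentMarkEvent
    distance_m: float
    interval_h: float


@dataclass
class ForaySummary:
    n_under_10min: int
    n_over_10min: int
    mean_min: float
    sd_min: float
    total_min: float
    percent_extraterritorial: float
    frequency_per_min: float
    split_min: float = 10.0
    #: declared definition of the frequency column
    frequency_definition: str = "forays per deployment minute"

    @property
    def n_forays(self) -> int:
        return self.n_under_10min + self.n_over_10min

    def to_dict(self) -> dict:
        return {
            "n_under_10min": self.n_under_10min,
            "n_over_10min": self.n_over_10min,
            "mean_min": self.mean_min,
            "sd_min": self.sd_min,
            "total_min": self.total_min,
            "percent_extraterritorial": self.percent_extraterritorial,
            "frequency_per_min": self.frequency_per_min,
            "split_min": self.split_min,
            "frequency_definition": self.frequency_definition,
        }


def mcp(points: np.ndarray, percent: float = 95.0) -> McpResult:
    """Percent minimum convex polygon.

    Peels ``ceil((1 - percent/100) * n)`` points farthest from the arithmetic
    centroid (ties: larger distance first, then later index), then takes the
    convex hull of the remainder.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    n_peel = math.ceil((1.0 - percent / 100.0) * n)
    # sort by (distance desc, index desc): those are peeled first
    order = sorted(range(n), key=lambda i: (-d[i], -i))
    keep = sorted(order[n_peel:])
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} points remain after peeling; need >= 3"
        )
    hull = MultiPoint(pts[keep].tolist()).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("retained points are collinear; MCP is degenerate")
    return McpResult(
        polygon=hull,
        area_m2=float(hull.area),
        percent=percent,
        n_points_in=len(keep),
        n_points_total=n,
    )


def overlap_proportion(all_mcp: McpResult, scent_mcp: McpResult) -> float:
    """Fraction of the all-fix MCP that the scent-mark MCP also covers."""
    area_all = all_mcp.polygon.area
    if area_all == 0:
        raise ValueError("all-location MCP has zero area")
    return float(all_mcp.polygon.intersection(scent_mcp.polygon).area / area_all)


def detect_revisits(
    events: list[ScentMarkEvent],
    buffer_m: float = 10.0,
    all_pairs: bool = False,
) -> list[RevisitEvent]:
    """Marks placed within ``buffer_m`` of an earlier mark.

    By default each mark pairs with the *most recent* earlier mark inside the
    buffer, so the revisit interval is unambiguous; ``all_pairs=True`` pairs
    with every earlier mark inside the buffer instead.
    """
    located = [e for e in events if e.located]
    located.sort(key=lambda e: e.start_s)
    out: list[RevisitEvent] = []
    for i, later in enumerate(located):
        partners = []
        for earlier in located[:i]:
            dist = math.hypot(later.x_m - earlier.x_m, later.y_m - earlier.y_m)
            if dist <= buffer_m:
                partners.append((earlier, dist))
        if not partners:
            continue
        if not all_pairs:
            partners = [max(partners, key=lambda p: p[0].start_s)]
        for earlier, dist in partners:
            out.append(
                RevisitEvent(
                    earlier=earlier,
                    later=later,
                    distance_m=dist,
                    interval_h=(later.start_s - earlier.start_s) / 3600.0,
                )
            )
    return out


def mean_revisit_interval_h(revisits: list[RevisitEvent]) -> float | None:
    if not revisits:
        return None
    return float(np.mean([r.interval_h for r in revisits]))


def detect_forays(
    track: GpsTrack,
    territory: McpResult | Polygon,
    split_min: float = 10.0,
) -> tuple[list[Foray], ForaySummary]:
    """Segment a projected track into extra-territorial forays.

    A foray runs from the first fix outside the territory polygon to the last
    fix before re-entry (boundary counts as inside).  The summary splits
    forays at ``split_min`` minutes (a duration of exactly ``split_min``
    counts as under), and reports mean +/- sd duration, total minutes,
    percent of the deployment span, and forays per deployment minute.
    """
    poly = territory.polygon if isinstance(territory, McpResult) else territory
    if not track.projected:
        raise ValueError("track must be projected before foray detection")
    n = len(track)
    if n == 0:
        raise ValueError("empty track")
    outside = np.array(
        [not poly.covers(Point(x, y)) for x, y in track.xy()], dtype=bool
    )
    if outside.all():
        warnings.warn(
            "track is entirely outside the territory polygon", stacklevel=2
        )
    forays: list[Foray] = []
    i = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outside[j + 1]:
            j += 1
        seg = track.xy()[i : j + 1]
        disp = max(float(poly.exterior.distance(Point(x, y))) for x, y in seg)
        forays.append(
            Foray(
                start_t=float(track.t[i]),
                end_t=float(track.t[j]),
                n_fixes=j - i + 1,
                max_displacement_m=disp,
            )
        )
        i = j + 1
    durations = np.array([f.duration_min for f in forays], dtype=float)
    deployment_min = (float(track.t[-1]) - float(track.t[0])) / 60.0
    if len(forays):
        mean = float(durations.mean())
        sd = float(durations.std(ddof=1)) if len(forays) > 1 else 0.0
        total = float(durations.sum())
    else:
        mean = sd = total = 0.0
    summary = ForaySummary(
        n_under_10min=int(np.sum(durations <= split_min)),
        n_over_10min=int(np.sum(durations > split_min)),
        mean_min=mean,
        sd_min=sd,
        total_min=total,
        percent_extraterritorial=(
            100.0 * total / deployment_min if deployment_min > 0 else 0.0
        ),
        frequency_per_min=(
            len(forays) / deployment_min if deployment_min > 0 else 0.0
        ),
        split_min=split_min,
    )
    return forays, summary
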