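"""From per-sample predictions to 1 Hz series, discrete events and locations.

High-rate predictions are segmented into 1-second bins and reduced to the
modal class per bin, which reduces data volume and matches the cadence of the
GPS fixes.  Maximal runs of a scent class become discrete scent-mark events,
which are then georeferenced to the GPS fix nearest in time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .classes import BehaviourClass, is_scent
from .classifier import MetricsReport, evaluate
from .io import GpsTrack


@dataclass
class SmoothedSeries:
    """Contiguous 1-second behaviour bins."""

    bins: list[tuple[float, BehaviourClass]]
    bin_s: float = 1.0

    def __len__(self) -> int:
        return len(self.bins)

    def classes(self) -> np.ndarray:
        return np.array([c for _t, c in self.bins], dtype=object)

    def times(self) -> np.ndarray:
        return np.array([t for t, _c in self.bins], dtype=float)


@dataclass
class ScentMarkEvent:
    """One discrete scent-marking event, optionally georeferenced."""

    start_s: float
    end_s: float
    cls: BehaviourClass
    x_m: float | None = None
    y_m: float | None = None
    lon: float | None = None
    lat: float | None = None
    source_fix_t: float | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("event must have end_s > start_s")
        if self.cls == BehaviourClass.OTHER:
            raise ValueError("OTHER cannot form a scent-mark event")

    @property
    def located(self) -> bool:
        return self.x_m is not None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _modal_class(samples: list[BehaviourClass]) -> BehaviourClass:
    """Modal class of one bin.

    Ties: a scent class beats OTHER (biasing toward detection of the rare
    classes of interest); among tied scent classes the one with the longest
    consecutive run of samples wins, then lexicographic order.
    """
    counts = Counter(samples)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    scent_tied = [c for c in tied if is_scent(c)]
    if scent_tied:
        tied = scent_tied
    if len(tied) == 1:
        return tied[0]
    # longest consecutive run inside the bin
    best_run: dict[BehaviourClass, int] = {c: 0 for c in tied}
    run_cls, run_len = None, 0
    for c in samples:
        if c == run_cls:
            run_len += 1
        else:
            run_cls, run_len = c, 1
        if c in best_run and run_len > best_run[c]:
            best_run[c] = run_len
    longest = max(best_run.values())
    tied = [c for c in tied if best_run[c] == longest]
    return min(tied, key=lambda c: c.value)


def smooth_modal(
    pred: Sequence[BehaviourClass],
    t: np.ndarray,
    rate_hz: float = 50.0,
    t0: float | None = None,
) -> SmoothedSeries:
    """Reduce per-sample predictions to the modal class of each 1 s bin.

    A partial trailing bin is kept only if at least half full (relative to
    ``rate_hz`` samples per bin).
    """
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        raise ValueError("cannot smooth an empty prediction series")
    if len(t) != len(pred):
        raise ValueError("pred and t lengths differ")
    if t0 is None:
        t0 = float(t[0])
    bin_idx = np.floor(t - t0).astype(int)
    if bin_idx.min() < 0:
        raise ValueError("t0 is after the first prediction timestamp")
    n_bins = int(bin_idx.max()) + 1
    bins: list[tuple[float, BehaviourClass]] = []
    order = np.argsort(bin_idx, kind="stable")
    boundaries = np.searchsorted(bin_idx[order], np.arange(n_bins + 1))
    for b in range(n_bins):
        members = order[boundaries[b] : boundaries[b + 1]]
        if len(members) == 0:
            bins.append((t0 + b, BehaviourClass.OTHER))  # gap bin
            continue
        if b == n_bins - 1 and len(members) < rate_hz / 2.0:
            break  # drop a <half-full trailing bin
        bins.append((t0 + b, _modal_class([pred[i] for i in members])))
    if not bins:
        raise ValueError("no bins survived smoothing")
    return SmoothedSeries(bins=bins)


def extract_events(
    series: SmoothedSeries, min_duration_s: float = 2.0
) -> list[ScentMarkEvent]:
    """Maximal runs of one scent class -> events; short runs are dropped.

    OTHER never yields an event.  Event start is the run's first bin start
    (posture onset best marks the deposition point).
    """
    events: list[ScentMarkEvent] = []
    i, n = 0, len(series.bins)
    while i < n:
        t_i, c_i = series.bins[i]
        if not is_scent(c_i):
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and series.bins[j + 1][1] == c_i
            and series.bins[j + 1][0] - series.bins[j][0] <= series.bin_s + 1e-9
        ):
            j += 1
        start, end = t_i, series.bins[j][0] + series.bin_s
        if end - start >= min_duration_s:
            events.append(ScentMarkEvent(start_s=start, end_s=end, cls=c_i))
        i = j + 1
    return events


def georeference(
    events: list[ScentMarkEvent],
    track: GpsTrack,
    tolerance_s: float = 10.0,
) -> list[ScentMarkEvent]:
    """Attach to each event the GPS fix nearest in time to its start.

    Events with no fix within ``tolerance_s`` stay unlocated.  Returns new
    event objects; the input list is untouched.
    """
    if len(track) == 0:
        warnings.warn("empty GPS track: all events left unlocated", stacklevel=2)
        return [
            ScentMarkEvent(e.start_s, e.end_s, e.cls) for e in events
        ]
    if not track.projected:
        raise ValueError("track must be projected before georeferencing")
    out: list[ScentMarkEvent] = []
    for ev in events:
        i = int(np.searchsorted(track.t, ev.start_s))
        cands = [j for j in (i - 1, i) if 0 <= j < len(track)]
        j = min(cands, key=lambda j: abs(track.t[j] - ev.start_s))
        if abs(track.t[j] - ev.start_s) <= tolerance_s:
            out.append(
                ScentMarkEvent(
                    ev.start_s,
                    ev.end_s,
                    ev.cls,
                    x_m=float(track.x_m[j]),
                    y_m=float(track.y_m[j]),
                    lon=float(track.lon[j]),
                    lat=float(track.lat[j]),
                    source_fix_t=float(track.t[j]),
                )
            )
        else:
            out.append(ScentMarkEvent(ev.start_s, ev.end_s, ev.cls))
    return out


def behaviour_specific_accuracy(
    pred_series: SmoothedSeries, truth_series: SmoothedSeries
) -> MetricsReport:
    """Per-class metrics at 1 Hz plus "hit/total seconds" detection fractions.

    Detection fractions report, per scent class, how many of its true seconds
    were classified correctly — so performance on rare marking postures is
    not masked by abundant OTHER behaviour.
    """
    tp = pred_series.times()
    tt = truth_series.times()
    n = min(len(tp), len(tt))
    if n == 0 or not np.allclose(tp[:n], tt[:n]):
        raise ValueError("prediction and truth series are misaligned")
    y_pred = pred_series.classes()[:n]
    y_true = truth_series.classes()[:n]
    report = evaluate(y_true, y_pred)
    for c in sorted(set(y_true.tolist()), key=lambda c: c.value):
        if not is_scent(c):
            continue
        total = int(np.sum(y_true == c))
        hit = int(np.sum((y_true == c) & (y_pred == c)))
        report.detections[c] = (hit, total)
    return report


def marking_rate(n_marks: int, duration_hours: float, ndigits: int = 2) -> float:
    """Scent marks per hour, rounded (the per-deployment summary rate)."""
    if duration_hours <= 0:
        raise ValueError("duration_hours must be positive")
    return round(n_marks / duration_hours, ndigits)
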