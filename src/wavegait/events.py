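"""Pygopod plant-event analyses.

Plant events are related to leg-swing initiations: each event is assigned
a signed offset to the globally closest swing onset across all six legs
(positive = event after the onset), classified by the segment of that
swing. Offset histograms use the Freedman-Diaconis bin width; planting
rate normalises event counts by tracked time; an event-triggered average
shows body velocity around plants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    LEG_IDS,
    ParameterError,
    PlantEventList,
    UndefinedResult,
    segment_of,
)
from .kinematics import SwingStanceSeries

__all__ = [
    "EventAlignment",
    "TriggeredAverage",
    "align_events_to_swings",
    "fd_bin_width",
    "offset_histogram",
    "plant_rate",
    "event_triggered_velocity",
    "pearson_r2",
]


@dataclass
class EventAlignment:
    """Signed event-to-swing-onset offsets (s) with swing identity."""

    offsets: np.ndarray        # s; positive = event after swing initiation
    legs: np.ndarray           # leg id of the closest swing
    segments: np.ndarray       # thoracic segment of that leg
    bin_width: float           # FD bin width of the offsets, s

    def __len__(self) -> int:
        return int(self.offsets.size)


def align_events_to_swings(
    events: PlantEventList, ss: SwingStanceSeries
) -> EventAlignment:
    """Offset of each plant event to the initiation of the closest swing.

    The closest swing is taken over all six legs; the sign is positive
    when the event follows the onset.
    """
    onset_list = []
    for leg in LEG_IDS:
        for t in ss.onset_times(leg):
            onset_list.append((t, leg))
    if not onset_list:
        raise UndefinedResult("no swings available to align events against")
    onset_list.sort()
    times = np.array([t for t, _ in onset_list])
    legs = np.array([leg for _, leg in onset_list], dtype=object)

    ev = events.times
    offsets = np.empty(ev.size)
    ev_legs = np.empty(ev.size, dtype=object)
    for i, t in enumerate(ev):
        idx = np.searchsorted(times, t)
        lo = max(0, idx - 1)
        cands = np.arange(lo, min(idx + 1, times.size))
        k = cands[np.argmin(np.abs(times[cands] - t))]
        offsets[i] = t - times[k]
        ev_legs[i] = legs[k]
    segs = np.array([segment_of(l) for l in ev_legs], dtype=object)
    width = fd_bin_width(offsets) if ev.size >= 2 else float("nan")
    return EventAlignment(offsets=offsets, legs=ev_legs, segments=segs, bin_width=width)


def fd_bin_width(values: np.ndarray) -> float:
    """Freedman-Diaconis histogram bin width: ``2 * IQR / n**(1/3)``.

    With a degenerate IQR of 0 the width falls back to Sturges-count
    binning (range over ``ceil(log2 n) + 1`` bins; unit width if the
    range is also zero).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ParameterError("need at least 2 values for a bin width")
    iqr = float(stats.iqr(values))
    if iqr > 0:
        return 2.0 * iqr / n ** (1.0 / 3.0)
    k = int(np.ceil(np.log2(n))) + 1
    rng = float(np.max(values) - np.min(values))
    return rng / k if rng > 0 else 1.0


def offset_histogram(
    alignment: EventAlignment, width: float | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalised offset histogram (counts sum to 1) on FD-width bins.

    Bin edges are anchored so that 0 is an edge, making the sign of the
    modal bin meaningful.
    """
    x = alignment.offsets
    if x.size == 0:
        raise ParameterError("no events to histogram")
    w = width if width is not None else alignment.bin_width
    if not np.isfinite(w) or w <= 0:
        raise ParameterError("invalid bin width")
    lo = np.floor(np.min(x) / w) * w
    hi = np.ceil(np.max(x) / w) * w
    edges = np.arange(lo, hi + w / 2, w)
    if edges.size < 2:
        edges = np.array([lo, lo + w])
    counts, edges = np.histogram(x, bins=edges)
    return counts / counts.sum(), edges


def plant_rate(events: PlantEventList, tracked_time: float) -> float:
    """Planting rate in Hz: event count over total tracked time."""
    if tracked_time <= 0:
        raise ParameterError("tracked_time must be > 0")
    return len(events) / tracked_time


@dataclass
class TriggeredAverage:
    """Event-triggered, normalised mean velocity around plant events."""

    lags: np.ndarray        # s, symmetric about 0
    mean: np.ndarray        # normalised velocity per lag
    n_events: int
    normalisation: str      # 'mean' or 'zscore'


def event_triggered_velocity(
    velocity: np.ndarray,
    fps: float,
    events: PlantEventList,
    window_s: float = 1.0,
    normalisation: str = "mean",
) -> TriggeredAverage:
    """Average body velocity in a +/- ``window_s`` window around events.

    Events whose window extends past the record are dropped. The average
    trace is normalised by its own mean ('mean', default) or z-scored
    ('zscore'); a constant velocity therefore yields a flat trace at 1.0
    (or 0.0 for z-scoring).
    """
    velocity = np.asarray(velocity, dtype=float)
    w = int(round(window_s * fps))
    if w < 1 or 2 * w >= velocity.size:
        raise ParameterError("window must be positive and shorter than the record")
    snippets = []
    for f in events.frames:
        if f - w < 0 or f + w >= velocity.size:
            continue
        snippets.append(velocity[f - w : f + w + 1])
    if not snippets:
        raise UndefinedResult("no events with a full window inside the record")
    mean = np.mean(snippets, axis=0)
    if normalisation == "mean":
        m = float(np.mean(mean))
        if m != 0:
            mean = mean / m
    elif normalisation == "zscore":
        sd = float(np.std(mean))
        mean = (mean - np.mean(mean)) / sd if sd > 0 else mean - np.mean(mean)
    else:
        raise ParameterError("normalisation must be 'mean' or 'zscore'")
    lags = np.arange(-w, w + 1) / fps
    return TriggeredAverage(
        lags=lags, mean=mean, n_events=len(snippets), normalisation=normalisation
    )


def pearson_r2(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need matched samples of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def alignment_frame(alignment: EventAlignment, animal_id: str = "animal") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": animal_id,
            "offset_s": alignment.offsets,
            "leg": alignment.legs,
            "segment": alignment.segments,
        }
    )
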