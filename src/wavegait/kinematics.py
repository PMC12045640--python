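"""Leg kinematics: speed traces, swing/stance segmentation and summaries.

The chain is: leg-tip positions -> per-frame speed (Savitzky-Golay
smoothed) -> swing intervals by hysteresis thresholding -> cycle period,
swing/stance durations, duty cycles, stride lengths and intra-/
intersegmental phase differences.

Phase conventions: intrasegmental (left vs right within a segment) values
are magnitudes of offsets wrapped to [-180, 180); intersegmental values
(relative to an anchor leg, default T3L) are in [0, 360). Negative phase
means temporally earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .config import RunConfig
from .core import (
    LEG_IDS,
    SEGMENTS,
    LegTrackTable,
    ParameterError,
    UndefinedResult,
    circular_mean_deg,
    segment_of,
    wrap_deg_180,
)

__all__ = [
    "VelocitySeries",
    "SwingStanceSeries",
    "KinematicsSummary",
    "leg_speed",
    "segment_swings",
    "swing_durations",
    "stance_durations",
    "cycle_period",
    "per_leg_frequency",
    "duty_cycles",
    "stride_length",
    "intrasegmental_phase",
    "intersegmental_phase",
    "summarise",
]


@dataclass
class VelocitySeries:
    """Per-leg leg-tip speed in mm/s.

    ``speed[leg][i]`` is the speed over the frame step ``[i, i+1)``, i.e.
    series length is one less than the number of frames.
    """

    speed: Dict[str, np.ndarray]
    fps: float
    sg_window: int
    sg_order: int

    @property
    def n_samples(self) -> int:
        return next(iter(self.speed.values())).shape[0]


@dataclass
class SwingStanceSeries:
    """Per-leg swing intervals ``[start, end)`` in frames; the complement
    within the record is stance."""

    swings: Dict[str, List[Tuple[int, int]]]
    fps: float
    n_frames: int

    def onset_times(self, leg: str) -> np.ndarray:
        """Swing-onset times in seconds."""
        return np.array([s for s, _ in self.swings[leg]], dtype=float) / self.fps

    def swing_mask(self, leg: str) -> np.ndarray:
        mask = np.zeros(self.n_frames, dtype=bool)
        for s, e in self.swings[leg]:
            mask[max(0, s) : min(self.n_frames, e)] = True
        return mask


def leg_speed(track: LegTrackTable, cfg: RunConfig | None = None) -> VelocitySeries:
    """Per-frame leg-tip speed in mm/s, Savitzky-Golay smoothed.

    Velocity components come from forward differences scaled by
    ``fps * mm_per_px``; each component is low-pass filtered before the
    magnitude is taken, so the result is non-negative by construction.
    """
    cfg = cfg or RunConfig()
    window = cfg.resolve_sg_window(track.fps)
    if track.n_frames - 1 < window:
        raise ParameterError(
            f"track of {track.n_frames} frames is shorter than the smoothing "
            f"window ({window}); use a smaller sg_window"
        )
    speed: Dict[str, np.ndarray] = {}
    for leg in LEG_IDS:
        xy = track.legs[leg]
        vxy = np.diff(xy, axis=0) * track.fps * track.mm_per_px
        # smooth the vector velocity before rectifying: filtering after the
        # magnitude would turn zero-mean tracking noise into a positive
        # speed floor that the swing thresholds cannot remove
        smooth = savgol_filter(vxy, window, cfg.sg_order, axis=0)
        speed[leg] = np.linalg.norm(smooth, axis=1)
    return VelocitySeries(speed=speed, fps=track.fps, sg_window=window, sg_order=cfg.sg_order)


def _hysteresis_runs(v: np.ndarray, hi: float, lo: float) -> List[Tuple[int, int]]:
    """Maximal runs of v >= lo that contain at least one sample >= hi."""
    above_lo = v >= lo
    runs: List[Tuple[int, int]] = []
    i = 0
    n = v.shape[0]
    while i < n:
        if not above_lo[i]:
            i += 1
            continue
        j = i
        while j < n and above_lo[j]:
            j += 1
        if np.any(v[i:j] >= hi):
            runs.append((i, j))
        i = j
    return runs


def segment_swings(vel: VelocitySeries, cfg: RunConfig | None = None) -> SwingStanceSeries:
    """Segment each leg's speed trace into swing intervals.

    Entry threshold = ``swing_threshold_frac`` x the leg's 95th-percentile
    speed; hysteresis exit threshold is half of that; runs shorter than the
    minimum swing duration are discarded. An all-zero trace yields an empty
    series (a legitimately stationary leg, not an error).
    """
    cfg = cfg or RunConfig()
    min_frames = cfg.resolve_min_swing_frames(vel.fps)
    swings: Dict[str, List[Tuple[int, int]]] = {}
    for leg in LEG_IDS:
        v = vel.speed[leg]
        if not np.all(np.isfinite(v)):
            raise ParameterError(f"leg {leg}: non-finite velocity")
        peak = float(np.percentile(v, 95))
        if peak <= 0.0:
            swings[leg] = []
            continue
        hi = cfg.swing_threshold_frac * peak
        lo = hi / 2.0
        runs = [(s, e) for s, e in _hysteresis_runs(v, hi, lo) if e - s >= min_frames]
        swings[leg] = runs
    return SwingStanceSeries(swings=swings, fps=vel.fps, n_frames=vel.n_samples + 1)


def swing_durations(ss: SwingStanceSeries) -> Dict[str, np.ndarray]:
    """Swing durations in seconds (swing stop minus swing start)."""
    return {
        leg: np.array([(e - s) for s, e in ss.swings[leg]], dtype=float) / ss.fps
        for leg in LEG_IDS
    }


def stance_durations(ss: SwingStanceSeries) -> Dict[str, np.ndarray]:
    """Stance durations: gaps between consecutive swings of each leg, s."""
    out: Dict[str, np.ndarray] = {}
    for leg in LEG_IDS:
        iv = ss.swings[leg]
        if len(iv) < 2:
            out[leg] = np.array([], dtype=float)
            continue
        gaps = [iv[i + 1][0] - iv[i][1] for i in range(len(iv) - 1)]
        out[leg] = np.array(gaps, dtype=float) / ss.fps
    return out


def per_leg_frequency(ss: SwingStanceSeries) -> Dict[str, float]:
    """Mean swing-onset rate of each leg, Hz (NaN with < 2 swings)."""
    freqs: Dict[str, float] = {}
    for leg in LEG_IDS:
        t = ss.onset_times(leg)
        if t.size < 2 or t[-1] <= t[0]:
            freqs[leg] = float("nan")
        else:
            freqs[leg] = (t.size - 1) / (t[-1] - t[0])
    return freqs


def cycle_period(ss: SwingStanceSeries) -> float:
    """Per-animal cycle period: 1 over the mean per-leg cycle frequency."""
    freqs = np.array([f for f in per_leg_frequency(ss).values() if np.isfinite(f)])
    if freqs.size == 0:
        raise UndefinedResult("cycle period undefined: no leg has >= 2 swings")
    return float(1.0 / np.mean(freqs))


def duty_cycles(ss: SwingStanceSeries, period: float) -> Dict[str, Tuple[float, float]]:
    """Per-segment (swing duty, stance duty).

    Swing duty = mean swing duration of the segment's legs over the cycle
    period; stance duty is the complement, so the two sum to 1 exactly.
    """
    if period <= 0:
        raise ParameterError("period must be > 0")
    sw = swing_durations(ss)
    out: Dict[str, Tuple[float, float]] = {}
    for seg in SEGMENTS:
        vals = np.concatenate([sw[leg] for leg in LEG_IDS if segment_of(leg) == seg])
        if vals.size == 0:
            out[seg] = (float("nan"), float("nan"))
            continue
        swing_duty = float(np.mean(vals) / period)
        out[seg] = (swing_duty, 1.0 - swing_duty)
    return out


def stride_length(track: LegTrackTable, ss: SwingStanceSeries) -> Dict[str, np.ndarray]:
    """Net leg-tip displacement over each swing, mm.

    Note: this is leg-tip displacement per swing (not body advance per
    cycle); the two definitions differ for slipping substrates.
    """
    out: Dict[str, np.ndarray] = {}
    for leg in LEG_IDS:
        xy = track.leg_mm(leg)
        vals = []
        for s, e in ss.swings[leg]:
            s = max(0, min(s, track.n_frames - 1))
            e = max(0, min(e, track.n_frames - 1))
            vals.append(float(np.linalg.norm(xy[e] - xy[s])))
        out[leg] = np.array(vals, dtype=float)
    return out


def _nearest(values: np.ndarray, x: float) -> float:
    """Nearest element of sorted ``values`` to ``x``; ties -> earlier."""
    idx = np.searchsorted(values, x)
    cands = values[max(0, idx - 1) : idx + 1]
    deltas = np.abs(cands - x)
    return float(cands[np.argmin(deltas)])  # argmin picks the earlier on ties


def intrasegmental_phase(ss: SwingStanceSeries, period: float) -> Dict[str, float]:
    """Left-right phase offset within each segment, degrees.

    For each left-leg onset the nearest right-leg onset is found; the
    offset is mapped to degrees of the cycle, wrapped to [-180, 180), and
    the segment value is the circular mean of the magnitudes. NaN when a
    side has no swings.
    """
    if period <= 0:
        raise ParameterError("period must be > 0")
    out: Dict[str, float] = {}
    for seg in SEGMENTS:
        tl = ss.onset_times(seg + "L")
        tr = ss.onset_times(seg + "R")
        if tl.size == 0 or tr.size == 0:
            out[seg] = float("nan")
            continue
        deltas = np.array([_nearest(tr, t) - t for t in tl])
        deg = np.abs(wrap_deg_180(360.0 * deltas / period))
        out[seg] = circular_mean_deg(deg, low=0.0)
    return out


def intersegmental_phase(
    ss: SwingStanceSeries, period: float, anchor: str = "T3L"
) -> Dict[str, float]:
    """Phase of each segment's ipsilateral leg relative to the anchor leg.

    For every anchor onset, the next onset of the target leg is taken;
    offsets are mapped to degrees of the cycle and circularly averaged in
    [0, 360). The anchor's own segment reports 0 by construction.
    """
    if period <= 0:
        raise ParameterError("period must be > 0")
    side = anchor[2]
    ta = ss.onset_times(anchor)
    out: Dict[str, float] = {}
    for seg in SEGMENTS:
        target = seg + side
        tt = ss.onset_times(target)
        if ta.size == 0 or tt.size == 0:
            out[seg] = float("nan")
            continue
        degs = []
        for t0 in ta:
            idx = np.searchsorted(tt, t0)
            if idx >= tt.size:
                continue
            degs.append(360.0 * (tt[idx] - t0) / period)
        if not degs:
            out[seg] = float("nan")
            continue
        out[seg] = circular_mean_deg(np.asarray(degs) % 360.0, low=0.0)
    return out


@dataclass
class KinematicsSummary:
    """Per-animal kinematic summary (see module docstring for conventions)."""

    animal_id: str
    period: float
    swing_duration: Dict[str, float]       # per segment, s
    stance_duration: Dict[str, float]      # per segment, s
    duty: Dict[str, Tuple[float, float]]   # per segment (swing, stance)
    stride: Dict[str, float]               # per leg, mean mm
    intraseg_phase: Dict[str, float]       # per segment, deg
    interseg_phase: Dict[str, float]       # per segment vs anchor, deg
    anchor: str


def summarise(
    track: LegTrackTable, cfg: RunConfig | None = None, anchor: str = "T3L"
) -> KinematicsSummary:
    """Run the full kinematic chain on one animal."""
    cfg = cfg or RunConfig()
    vel = leg_speed(track, cfg)
    ss = segment_swings(vel, cfg)
    period = cycle_period(ss)
    sw = swing_durations(ss)
    st = stance_durations(ss)

    def seg_mean(d: Dict[str, np.ndarray]) -> Dict[str, float]:
        out = {}
        for seg in SEGMENTS:
            vals = np.concatenate([d[leg] for leg in LEG_IDS if segment_of(leg) == seg])
            out[seg] = float(np.mean(vals)) if vals.size else float("nan")
        return out

    strides = stride_length(track, ss)
    return KinematicsSummary(
        animal_id=track.animal_id,
        period=period,
        swing_duration=seg_mean(sw),
        stance_duration=seg_mean(st),
        duty=duty_cycles(ss, period),
        stride={leg: float(np.mean(v)) if v.size else float("nan") for leg, v in strides.items()},
        intraseg_phase=intrasegmental_phase(ss, period),
        interseg_phase=intersegmental_phase(ss, period, anchor),
        anchor=anchor,
    )


def summary_frame(summary: KinematicsSummary) -> pd.DataFrame:
    """Tidy one-row-per-segment table of a summary."""
    rows = []
    for seg in SEGMENTS:
        rows.append(
            {
                "animal": summary.animal_id,
                "segment": seg,
                "cycle_period_s": summary.period,
                "swing_duration_s": summary.swing_duration[seg],
                "stance_duration_s": summary.stance_duration[seg],
                "swing_duty": summary.duty[seg][0],
                "stance_duty": summary.duty[seg][1],
                "intraseg_phase_deg": summary.intraseg_phase[seg],
                "interseg_phase_deg": summary.interseg_phase[seg],
                "anchor": summary.anchor,
            }
        )
    return pd.DataFrame(rows)


def intervals_frame(ss: SwingStanceSeries, animal_id: str = "animal") -> pd.DataFrame:
    """Tidy per-swing interval table."""
    rows = []
    for leg in LEG_IDS:
        for k, (s, e) in enumerate(ss.swings[leg]):
            rows.append(
                {
                    "animal": animal_id,
                    "leg": leg,
                    "swing_idx": k,
                    "start_frame": s,
                    "end_frame": e,
                    "start_s": s / ss.fps,
                    "duration_s": (e - s) / ss.fps,
                }
            )
    return pd.DataFrame(rows)
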