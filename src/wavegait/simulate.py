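"""Synthetic gait, pygopod-event and exploration-path generator.

The generator emits data with the statistical structure the analysis chain
assumes, together with exact ground truth, so that every estimator can be
validated by parameter recovery:

* six phase-coupled legs stepping as a bilaterally symmetric
  posterior-to-anterior (metachronal) wave: the metathoracic pair (T3)
  swings first, the mesothoracic pair (T2) follows after an
  intersegmental lag (default 120 deg of the cycle) and the prothoracic
  pair (T1) after twice the lag; left and right legs of a segment are
  synchronous up to jitter,
* constant swing duration with the stance absorbing period changes (the
  slow-walking regime is modelled as a longer period at the same swing
  duration, plus optional swing dropout and intrasegmental jitter),
* pygopod plant events triggered probabilistically at swing initiations
  with Gaussian timing jitter,
* 2-D exploration paths with headsweeps, pauses and
  backtrack-and-redirect episodes, with per-frame behavioural labels.

Swing velocity follows a half-sine pulse over the swing duration (smooth,
zero at both endpoints, analytic peak speed), so the leg tip is stationary
in the lab frame during stance and advances by one stride per swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .core import (
    LEG_IDS,
    CentroidTrack,
    LegTrackTable,
    ParameterError,
    PlantEventList,
    segment_of,
)

__all__ = [
    "GaitParams",
    "PathParams",
    "GaitGroundTruth",
    "PathGroundTruth",
    "simulate_gait",
    "simulate_path",
]


@dataclass
class GaitParams:
    """Parameters of the six-leg gait simulation.

    Defaults describe fast straight walking: cycle period 0.2 s, constant
    swing duration 0.07 s, 120 deg intersegmental lag, no jitter or
    dropout, recorded at 60 frames/s. The slow regime is obtained by
    raising ``period`` (e.g. 0.7 s) while keeping ``swing_duration``
    fixed, optionally with ``skip_prob`` > 0 and intrasegmental jitter.
    """

    period: float = 0.2                 # s, cycle period T
    swing_duration: float = 0.07        # s, constant across speeds
    interseg_lag_deg: float = 120.0     # T3->T2 and T2->T1 phase lag
    intraseg_jitter_sd_deg: float = 0.0
    skip_prob: float = 0.0              # P(scheduled swing dropped)
    speed: float = 1.8                  # mm/s, nominal forward speed
    stride_gain: float = 0.2            # mm per (mm/s): stride = gain * speed
    noise_sd: float = 0.0               # mm/s Gaussian noise on leg velocity
    pygopod_prob: float = 0.089         # P(plant event at a swing onset):
                                        # at a 0.7 s period (6 legs stepping at
                                        # ~8.6 onsets/s) this yields the ~0.76 Hz
                                        # planting rate typical of overhang climbing
    pygopod_jitter_sd: float = 0.02     # s
    fps: float = 60.0
    mm_per_px: float = 0.01
    n_cycles: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swing_duration >= self.period:
            raise ParameterError("swing_duration must be < period")
        if self.fps * self.period < 4:
            raise ParameterError("need at least 4 frames per cycle (fps * period >= 4)")
        if not (0.0 <= self.skip_prob < 1.0):
            raise ParameterError("skip_prob must be in [0, 1)")
        if not (0.0 <= self.pygopod_prob <= 1.0):
            raise ParameterError("pygopod_prob must be in [0, 1]")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")

    @property
    def stride_mm(self) -> float:
        return self.stride_gain * self.speed


@dataclass
class GaitGroundTruth:
    """Exact generator state for a simulated gait bout."""

    period: float
    swing_duration: float
    phase_deg: Dict[str, float]                    # per leg, deg of cycle
    swing_times: Dict[str, List[Tuple[float, float]]]   # (start, end) s
    swing_frames: Dict[str, List[Tuple[int, int]]]      # [start, end) frames
    plant_times: np.ndarray                        # s
    stride_mm: float
    n_frames: int
    fps: float

    def swing_mask(self, leg: str, n: int | None = None) -> np.ndarray:
        """Boolean per-frame swing indicator for one leg."""
        n = self.n_frames if n is None else n
        mask = np.zeros(n, dtype=bool)
        for s, e in self.swing_frames[leg]:
            mask[max(0, s) : min(n, e)] = True
        return mask


def _leg_phases(lag: float) -> Dict[str, float]:
    seg_phase = {"T3": 0.0, "T2": lag, "T1": 2.0 * lag}
    return {leg: seg_phase[segment_of(leg)] for leg in LEG_IDS}


def _half_sine_profile(t: np.ndarray, t0: float, s_w: float) -> np.ndarray:
    """Fraction of the stride completed at times ``t`` for a swing at t0."""
    u = np.clip((t - t0) / s_w, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def simulate_gait(
    params: GaitParams,
) -> Tuple[LegTrackTable, GaitGroundTruth, PlantEventList]:
    """Simulate one straight-walking bout.

    Returns the pixel-space leg-track table, the exact ground truth and
    the simulated pygopod plant events. Leg ``k``'s swing onsets sit at
    ``n*T + (phase_k/360)*T + jitter``; a scheduled swing is dropped with
    probability ``skip_prob``. A trailing metathoracic (T3) onset closes
    the final cycle so that all ``n_cycles`` cycles are complete.
    """
    rng = np.random.default_rng(params.seed)
    T, s_w, fps = params.period, params.swing_duration, params.fps
    phases = _leg_phases(params.interseg_lag_deg)

    total_s = params.n_cycles * T + s_w + 2.0 / fps
    n_frames = int(round(total_s * fps)) + 1
    t_frames = np.arange(n_frames) / fps

    swing_times: Dict[str, List[Tuple[float, float]]] = {}
    for leg in LEG_IDS:
        onsets = []
        last_cycle = params.n_cycles + 1 if segment_of(leg) == "T3" else params.n_cycles
        for n in range(last_cycle):
            t0 = n * T + (phases[leg] / 360.0) * T
            if params.intraseg_jitter_sd_deg > 0:
                t0 += rng.normal(0.0, params.intraseg_jitter_sd_deg) / 360.0 * T
            closing = segment_of(leg) == "T3" and n == params.n_cycles
            if not closing and params.skip_prob > 0 and rng.random() < params.skip_prob:
                continue
            onsets.append(t0)
        swing_times[leg] = [(t0, min(t0 + s_w, t_frames[-1])) for t0 in sorted(onsets)]

    # leg-tip trajectories (mm), then converted to px
    base_y = {"L": 1.0, "R": -1.0}
    base_x = {"T1": 2.0, "T2": 1.0, "T3": 0.0}
    legs_px: Dict[str, np.ndarray] = {}
    for leg in LEG_IDS:
        x = np.full(n_frames, base_x[segment_of(leg)], dtype=float)
        for t0, _ in swing_times[leg]:
            x += params.stride_mm * _half_sine_profile(t_frames, t0, s_w)
        y = np.full(n_frames, base_y[leg[2]], dtype=float)
        if params.noise_sd > 0:
            # white velocity noise: the added 2-D perturbation vector has
            # sd noise_sd (mm/s), i.e. noise_sd/sqrt(2) per component;
            # integrated to per-frame displacement perturbations
            step_sd = params.noise_sd / fps / np.sqrt(2.0)
            x += np.concatenate(([0.0], np.cumsum(rng.normal(0.0, step_sd, n_frames - 1))))
            y += np.concatenate(([0.0], np.cumsum(rng.normal(0.0, step_sd, n_frames - 1))))
        legs_px[leg] = np.column_stack([x, y]) / params.mm_per_px

    table = LegTrackTable(
        fps=fps,
        mm_per_px=params.mm_per_px,
        legs=legs_px,
        animal_id=f"sim-gait-seed{params.seed}",
    )

    swing_frames = {
        leg: [
            (int(round(t0 * fps)), int(round(t1 * fps)))
            for t0, t1 in swing_times[leg]
        ]
        for leg in LEG_IDS
    }

    # plant events: each swing onset triggers a plant with prob pygopod_prob
    plant_times: List[float] = []
    for leg in LEG_IDS:
        for t0, _ in swing_times[leg]:
            if rng.random() < params.pygopod_prob:
                plant_times.append(t0 + rng.normal(0.0, params.pygopod_jitter_sd))
    plant_times_arr = np.sort(np.array(plant_times))
    plant_frames = np.round(plant_times_arr * fps).astype(int)
    keep = (plant_frames >= 0) & (plant_frames < n_frames)
    plant_frames = np.unique(plant_frames[keep])

    truth = GaitGroundTruth(
        period=T,
        swing_duration=s_w,
        phase_deg=phases,
        swing_times=swing_times,
        swing_frames=swing_frames,
        plant_times=plant_times_arr[keep],
        stride_mm=params.stride_mm,
        n_frames=n_frames,
        fps=fps,
    )
    events = PlantEventList(
        frames=plant_frames, fps=fps, n_frames=n_frames, source="simulated"
    )
    return table, truth, events


# ---------------------------------------------------------------------------
# exploration paths
# ---------------------------------------------------------------------------


@dataclass
class PathParams:
    """Parameters of the 2-D exploration-path simulation.

    Defaults describe unchallenged exploration on a flat substrate:
    mean speed 1.8 mm/s, occasional headsweeps, rare pauses and
    backtrack-and-redirect episodes lasting 3-6 s.
    """

    mean_speed: float = 1.8             # mm/s
    headsweep_rate: float = 0.2         # episodes / s
    headsweep_magnitude_deg: float = 60.0   # peak |angle - 180| during a sweep
    backtrack_rate: float = 0.02        # episodes / s
    backtrack_duration_s: Tuple[float, float] = (3.0, 6.0)
    pause_prob: float = 0.005           # P(enter pause) per second
    heading_noise_sd_deg: float = 1.5   # per-frame heading random walk
    angle_noise_sd_deg: float = 4.0     # body-angle wobble around 180
    duration: float = 120.0             # s
    fps: float = 30.0
    mm_per_px: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if min(self.headsweep_rate, self.backtrack_rate, self.pause_prob) < 0:
            raise ParameterError("rates must be >= 0")
        lo, hi = self.backtrack_duration_s
        if not (0 < lo <= hi):
            raise ParameterError("backtrack_duration_s must be 0 < lo <= hi")
        if self.headsweep_magnitude_deg < 30.0:
            raise ParameterError(
                "headsweep_magnitude_deg must be >= 30 so sweeps cross the "
                "210/150 deg thresholds"
            )


@dataclass
class PathGroundTruth:
    """Per-frame labels and episode list for a simulated path."""

    states: np.ndarray               # 'straight' | 'bent' | 'still'
    headsweep: np.ndarray            # 'left' | 'right' | 'none'
    backtrack_episodes: List[Tuple[int, int, str]]  # [start, end) frames, first-turn side
    mean_speed: float
    fps: float


def _sweep_profile(n: int, peak: float) -> np.ndarray:
    """Smooth angular excursion, zero at both ends, max ``peak``."""
    return peak * np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2


def simulate_path(params: PathParams) -> Tuple[CentroidTrack, PathGroundTruth]:
    """Simulate a centroid trajectory with labelled behavioural states.

    The heading performs a random walk; headsweep episodes push the body
    angle beyond the 210/150 deg thresholds and rotate the heading; pauses
    set speed to zero; a backtrack-and-redirect episode is a turn to one
    side, a stretch of backwards locomotion at a straight body angle, and
    a contralateral turn before forward motion resumes.
    """
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    n = int(round(params.duration * fps))
    if n < 2:
        raise ParameterError("duration too short for the frame rate")

    # mean_speed is the bout-average instantaneous velocity. Episodes run
    # slower than cruising (sweeps at 0.5x, backtrack phases at ~0.54x,
    # pauses at 0), so the cruise speed is solved from the expected time
    # budget of each episode type to keep the time average on target.
    f_sweep = params.headsweep_rate * 0.75
    f_back = params.backtrack_rate * 0.5 * sum(params.backtrack_duration_s)
    f_pause = params.pause_prob * 1.25
    denom = 1.0 - 0.5 * f_sweep - 0.46 * f_back - f_pause
    if denom <= 0.1:
        raise ParameterError("episode rates leave too little cruising time")
    cruise = params.mean_speed / denom

    speed = np.full(n, cruise)
    angle = np.full(n, 180.0)
    heading = np.zeros(n)
    sweep_flag = np.full(n, "none", dtype=object)
    state = np.full(n, "straight", dtype=object)
    episodes: List[Tuple[int, int, str]] = []

    p_sweep = params.headsweep_rate / fps
    p_back = params.backtrack_rate / fps
    p_pause = params.pause_prob / fps

    h = rng.uniform(0.0, 360.0) if params.heading_noise_sd_deg > 0 else 0.0
    i = 0
    while i < n:
        u = rng.random()
        if u < p_back:
            i, h = _emit_backtrack(params, rng, cruise, i, h, speed, angle,
                                   heading, episodes, n)
            continue
        if u < p_back + p_sweep:
            i, h = _emit_headsweep(params, rng, cruise, i, h, speed, angle,
                                   heading, n)
            continue
        if u < p_back + p_sweep + p_pause:
            dur = int(round(rng.uniform(0.5, 2.0) * fps))
            j = min(n, i + max(dur, 1))
            speed[i:j] = 0.0
            angle[i:j] = 180.0 + (
                rng.normal(0.0, params.angle_noise_sd_deg) if params.angle_noise_sd_deg > 0 else 0.0
            )
            heading[i:j] = h
            state[i:j] = "still"
            i = j
            continue
        # cruise frame
        if params.heading_noise_sd_deg > 0:
            h += rng.normal(0.0, params.heading_noise_sd_deg)
        heading[i] = h
        if params.angle_noise_sd_deg > 0:
            angle[i] = 180.0 + rng.normal(0.0, params.angle_noise_sd_deg)
        i += 1

    # integrate positions (mm): still frames contribute nothing; during
    # backtrack the stored heading already points backwards.
    hrad = np.deg2rad(heading)
    step = (speed / fps)[:, None] * np.column_stack([np.cos(hrad), np.sin(hrad)])
    xy_mm = np.vstack([[0.0, 0.0], np.cumsum(step[:-1], axis=0)])

    # derive per-frame labels consistent with the emitted kinematics
    sweep_left = angle >= 210.0
    sweep_right = angle <= 150.0
    sweep_flag = np.where(sweep_left, "left", np.where(sweep_right, "right", "none")).astype(object)
    still = speed <= 1e-9
    straight = (~still) & (np.abs(angle - 180.0) <= 30.0)
    state = np.where(still, "still", np.where(straight, "straight", "bent")).astype(object)

    track = CentroidTrack(
        fps=fps,
        mm_per_px=params.mm_per_px,
        xy=xy_mm / params.mm_per_px,
        angle_deg=angle,
        animal_id=f"sim-path-seed{params.seed}",
    )
    truth = PathGroundTruth(
        states=state,
        headsweep=sweep_flag,
        backtrack_episodes=episodes,
        mean_speed=params.mean_speed,
        fps=fps,
    )
    return track, truth


def _emit_headsweep(params, rng, cruise, i, h, speed, angle, heading, n):
    fps = params.fps
    dur = max(3, int(round(rng.uniform(0.5, 1.0) * fps)))
    j = min(n, i + dur)
    side = 1.0 if rng.random() < 0.5 else -1.0     # +1 = left (angle > 180)
    prof = _sweep_profile(j - i, params.headsweep_magnitude_deg)
    angle[i:j] = 180.0 + side * prof
    speed[i:j] = 0.5 * cruise
    turn = side * rng.uniform(30.0, 60.0)
    heading[i:j] = h + turn * np.linspace(0.0, 1.0, j - i)
    return j, h + turn


def _emit_backtrack(params, rng, cruise, i, h, speed, angle, heading,
                    episodes, n):
    fps = params.fps
    lo, hi = params.backtrack_duration_s
    total = rng.uniform(lo, hi)
    n1 = max(3, int(round(0.25 * total * fps)))    # first turn
    n2 = max(3, int(round(0.40 * total * fps)))    # backwards run
    n3 = max(3, int(round(0.25 * total * fps)))    # contralateral turn
    n4 = max(1, int(round(0.10 * total * fps)))    # forward resumption
    j = i + n1 + n2 + n3 + n4
    if j > n:          # episode would not fit; cruise out the remainder
        heading[i:n] = h
        return n, h
    side = 1.0 if rng.random() < 0.5 else -1.0
    first = "left" if side > 0 else "right"
    k = i
    angle[k : k + n1] = 180.0 + side * _sweep_profile(n1, params.headsweep_magnitude_deg)
    speed[k : k + n1] = 0.4 * cruise
    heading[k : k + n1] = h
    k += n1
    # backwards locomotion at straight body angle: heading flipped
    angle[k : k + n2] = 180.0
    speed[k : k + n2] = 0.6 * cruise
    heading[k : k + n2] = h + 180.0
    k += n2
    angle[k : k + n3] = 180.0 - side * _sweep_profile(n3, params.headsweep_magnitude_deg)
    speed[k : k + n3] = 0.4 * cruise
    heading[k : k + n3] = h
    k += n3
    new_h = h - side * rng.uniform(40.0, 80.0)
    angle[k : k + n4] = 180.0
    speed[k : k + n4] = cruise
    heading[k : k + n4] = new_h
    episodes.append((i, j, first))
    return j, new_h
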