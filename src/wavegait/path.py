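"""Whole-animal path metrics and behavioural-state analysis.

Works on centroid trajectories with a per-frame body-bending angle
(180 deg = straight). Frames are classified into straight / bent / still;
headsweeps are flagged by the 210 deg (left) and 150 deg (right) angle
thresholds; backtrack-and-redirect episodes (turn, backwards locomotion,
contralateral turn) are detected by a small state machine over the
headsweep sequence and the displacement projected on the prior heading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CentroidTrack, ParameterError, UndefinedResult

__all__ = [
    "BehaviouralStateSeries",
    "Episode",
    "instantaneous_velocity",
    "classify_states",
    "headsweep_episodes",
    "headsweep_bias",
    "detect_backtrack_redirect",
    "curviness",
    "angle_histogram",
    "total_distance",
]

LEFT_SWEEP_DEG = 210.0
RIGHT_SWEEP_DEG = 150.0


def instantaneous_velocity(track: CentroidTrack) -> np.ndarray:
    """Per-step speed in mm/s (length ``n_frames - 1``)."""
    d = np.diff(track.xy_mm, axis=0)
    return np.linalg.norm(d, axis=1) * track.fps


@dataclass
class BehaviouralStateSeries:
    """Per-frame behavioural state and headsweep flag."""

    states: np.ndarray       # 'straight' | 'bent' | 'still'
    headsweep: np.ndarray    # 'left' | 'right' | 'none'
    tol_angle: float
    tol_vel: float

    def proportions(self) -> dict:
        n = self.states.size
        return {s: float(np.sum(self.states == s)) / n for s in ("straight", "bent", "still")}


def classify_states(
    track: CentroidTrack, tol_angle: float = 30.0, tol_vel: float = 0.05
) -> BehaviouralStateSeries:
    """Classify every frame as straight, bent or still.

    A frame is still when speed <= ``tol_vel`` mm/s (a literal 0 mm/s
    never occurs in floating point); otherwise straight when the body
    angle is within ``tol_angle`` of 180 deg, else bent. Headsweep flags
    come from the 210/150 deg thresholds independently of the
    three-state label.
    """
    v = instantaneous_velocity(track)
    v_frame = np.append(v, v[-1])          # last frame inherits the last step
    angle = track.angle_deg
    still = v_frame <= tol_vel
    straight = (~still) & (np.abs(angle - 180.0) <= tol_angle)
    states = np.where(still, "still", np.where(straight, "straight", "bent")).astype(object)
    sweep = np.where(
        angle >= LEFT_SWEEP_DEG, "left",
        np.where(angle <= RIGHT_SWEEP_DEG, "right", "none"),
    ).astype(object)
    return BehaviouralStateSeries(states=states, headsweep=sweep,
                                  tol_angle=tol_angle, tol_vel=tol_vel)


def headsweep_episodes(series: BehaviouralStateSeries) -> List[Tuple[int, int, str]]:
    """Maximal runs of a single headsweep side: ``[start, end), side``."""
    out: List[Tuple[int, int, str]] = []
    flags = series.headsweep
    i = 0
    n = flags.size
    while i < n:
        if flags[i] == "none":
            i += 1
            continue
        side = flags[i]
        j = i
        while j < n and flags[j] == side:
            j += 1
        out.append((i, j, str(side)))
        i = j
    return out


def headsweep_bias(left: int, right: int) -> Tuple[float, float]:
    """Test whether headsweeps favour one side.

    Fits an intercept-only binomial model of left-vs-right counts, which
    is a test of left proportion = 0.5. Returns (estimated left
    proportion, two-sided p). The exact binomial p-value is used when the
    counts are completely one-sided (where a Wald test degenerates).
    """
    if left < 0 or right < 0 or left + right < 1:
        raise ParameterError("need at least one headsweep event")
    n = left + right
    est = left / n
    if left == 0 or right == 0:
        p = stats.binomtest(left, n, 0.5).pvalue
        return float(est), float(p)
    import statsmodels.api as sm

    endog = np.concatenate([np.ones(left), np.zeros(right)])
    model = sm.GLM(endog, np.ones((n, 1)), family=sm.families.Binomial())
    res = model.fit()
    return float(est), float(res.pvalues[0])


@dataclass
class Episode:
    """A backtrack-and-redirect episode."""

    start: int                 # frame, inclusive
    end: int                   # frame, exclusive
    first_turn: str            # 'left' | 'right'
    backtrack_mm: float        # backwards displacement along prior heading

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)


def _heading_before(track: CentroidTrack, frame: int, window_s: float) -> np.ndarray | None:
    """Unit heading from the displacement over ``window_s`` before ``frame``."""
    w = max(1, int(round(window_s * track.fps)))
    lo = max(0, frame - w)
    if frame <= lo:
        return None
    d = track.xy_mm[frame] - track.xy_mm[lo]
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return None
    return d / norm


def detect_backtrack_redirect(
    track: CentroidTrack,
    tol_angle: float = 30.0,
    min_backtrack_mm: float = 0.3,
    max_duration_s: float = 8.0,
    heading_window_s: float = 0.5,
) -> List[Episode]:
    """Detect backtrack-and-redirect episodes.

    State machine: (i) a headsweep to one side; (ii) a stretch where the
    displacement projected on the pre-episode heading is negative by at
    least ``min_backtrack_mm`` while the body is near-straight
    (|angle - 180| <= ``tol_angle``); (iii) a headsweep to the opposite
    side, all within ``max_duration_s`` of the first sweep's start.
    A straight constant-velocity path yields no episodes.
    """
    series = classify_states(track, tol_angle=tol_angle)
    sweeps = headsweep_episodes(series)
    angle = track.angle_deg
    steps = np.diff(track.xy_mm, axis=0)
    max_frames = int(round(max_duration_s * track.fps))

    episodes: List[Episode] = []
    used_until = -1
    for (s1, e1, side1), (s2, e2, side2) in zip(sweeps, sweeps[1:]):
        # only the immediately following sweep qualifies: the behaviour is
        # turn -> backwards run -> contralateral turn with nothing between
        if s1 <= used_until or side2 == side1:
            continue
        if s2 - s1 > max_frames or s2 <= e1:
            continue
        h0 = _heading_before(track, s1, heading_window_s)
        if h0 is None:
            continue
        proj = steps[e1:s2] @ h0
        net = float(np.sum(proj))
        straightish = np.abs(angle[e1:s2] - 180.0) <= tol_angle
        if net < -min_backtrack_mm and np.mean(straightish) >= 0.5:
            episodes.append(
                Episode(start=s1, end=e2, first_turn=side1, backtrack_mm=-net)
            )
            used_until = e2 - 1
    return episodes


def curviness(track_or_xy: CentroidTrack | np.ndarray) -> float:
    """Path tortuosity: total path length over net displacement (>= 1).

    Invariant to rotation, translation and uniform scaling; raises
    :class:`UndefinedResult` for zero net displacement.
    """
    xy = track_or_xy.xy_mm if isinstance(track_or_xy, CentroidTrack) else np.asarray(track_or_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise ParameterError("need at least two path vertices")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    if net < 1e-12:
        raise UndefinedResult("zero net displacement: curviness undefined")
    return float(np.sum(steps) / net)


def angle_histogram(
    track: CentroidTrack, bin_deg: float = 10.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Body-angle counts binned every ``bin_deg`` degrees over [0, 360)."""
    edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
    counts, edges = np.histogram(np.mod(track.angle_deg, 360.0), bins=edges)
    return counts, edges


def total_distance(track: CentroidTrack) -> float:
    """Total path length in mm."""
    return float(np.sum(np.linalg.norm(np.diff(track.xy_mm, axis=0), axis=1)))


def states_frame(series: BehaviouralStateSeries, fps: float,
                 animal_id: str = "animal") -> pd.DataFrame:
    n = series.states.size
    return pd.DataFrame(
        {
            "animal": animal_id,
            "frame": np.arange(n),
            "time_s": np.arange(n) / fps,
            "state": series.states,
            "headsweep": series.headsweep,
        }
    )
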