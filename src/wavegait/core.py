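"""Shared containers for six-leg tracking data and whole-animal trajectories.

Conventions used throughout the package:

* frames are 0-based integers; intervals are half-open ``[start, end)`` in
  frames; every reported duration is in seconds,
* leg identifiers are ``T1L ... T3R`` (segment T1 = prothorax, anterior;
  T3 = metathorax, posterior; L/R = animal's left/right),
* raw coordinates are in pixels; a ``mm_per_px`` scale converts to mm and
  all derived kinematic quantities are in SI-ish units (mm, s, mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

LEG_IDS: Tuple[str, ...] = ("T1L", "T1R", "T2L", "T2R", "T3L", "T3R")
SEGMENTS: Tuple[str, ...] = ("T1", "T2", "T3")


def segment_of(leg: str) -> str:
    """Thoracic segment ('T1'|'T2'|'T3') a leg id belongs to."""
    return leg[:2]


def side_of(leg: str) -> str:
    """'L' or 'R'."""
    return leg[2]


class IngestionError(ValueError):
    """Raised when an input table violates the dialect contract."""


class ParameterError(ValueError):
    """Raised for invalid configuration or simulation parameters."""


class UndefinedResult(ValueError):
    """Raised when a quantity is mathematically undefined for the input
    (e.g. a fundamental frequency of an all-zero trace)."""


@dataclass
class LegTrackTable:
    """Per-frame leg-tip positions for all six legs of one animal.

    Attributes
    ----------
    fps : float
        Acquisition frame rate, frames/second.
    mm_per_px : float
        Spatial scale of the raw pixel coordinates.
    legs : dict
        Maps each leg id in :data:`LEG_IDS` to an ``(n_frames, 2)`` float
        array of (x, y) pixel positions.
    animal_id : str
        Free-form identifier carried through to output tables.
    """

    fps: float
    mm_per_px: float
    legs: Dict[str, np.ndarray]
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be > 0")
        missing = set(LEG_IDS) - set(self.legs)
        if missing:
            raise IngestionError(f"missing legs: {sorted(missing)}")
        extra = set(self.legs) - set(LEG_IDS)
        if extra:
            raise IngestionError(f"unknown leg ids: {sorted(extra)}")
        lengths = set()
        for leg in LEG_IDS:
            arr = np.asarray(self.legs[leg], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise IngestionError(f"leg {leg}: expected (n, 2) coordinates")
            if not np.all(np.isfinite(arr)):
                raise IngestionError(f"leg {leg}: non-finite coordinates (gap?)")
            self.legs[leg] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise IngestionError(f"legs differ in length: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise IngestionError("tracks must span at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.legs[LEG_IDS[0]].shape[0]

    @property
    def duration(self) -> float:
        """Total tracked time in seconds (n_frames / fps)."""
        return self.n_frames / self.fps

    def leg_mm(self, leg: str) -> np.ndarray:
        """Positions of one leg in mm."""
        return self.legs[leg] * self.mm_per_px


@dataclass
class CentroidTrack:
    """Whole-animal centroid trajectory with per-frame body-bending angle.

    The bending angle follows the convention of larva trackers: 180 deg is a
    straight body; >180 deg bends to the animal's left, <180 deg to the right.
    """

    fps: float
    mm_per_px: float
    xy: np.ndarray            # (n, 2) px
    angle_deg: np.ndarray     # (n,)
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be > 0")
        self.xy = np.asarray(self.xy, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise IngestionError("xy must be (n, 2)")
        if self.angle_deg.shape != (self.xy.shape[0],):
            raise IngestionError("angle_deg length must match xy")
        if self.xy.shape[0] < 2:
            raise IngestionError("track must span at least 2 frames")
        if not np.all(np.isfinite(self.xy)) or not np.all(np.isfinite(self.angle_deg)):
            raise IngestionError("non-finite values in centroid track")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def xy_mm(self) -> np.ndarray:
        return self.xy * self.mm_per_px


@dataclass
class PlantEventList:
    """Frame indices of pygopod planting events on a given frame clock.

    ``source`` records provenance: manually annotated events versus
    simulator ground truth.
    """

    frames: np.ndarray
    fps: float
    n_frames: int | None = None
    source: str = "observed"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise IngestionError("event frames must be strictly increasing")
        if self.frames.size and self.frames[0] < 0:
            raise IngestionError("negative event frame")
        if self.n_frames is not None and self.frames.size and self.frames[-1] >= self.n_frames:
            raise IngestionError(
                f"event frame {int(self.frames[-1])} outside track of {self.n_frames} frames"
            )

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds."""
        return self.frames / self.fps

    def __len__(self) -> int:
        return int(self.frames.size)


def wrap_deg_180(deg):
    """Wrap angles to [-180, 180)."""
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def wrap_deg_360(deg):
    """Wrap angles to [0, 360)."""
    return np.asarray(deg) % 360.0


def circular_mean_deg(deg: np.ndarray, low: float = 0.0) -> float:
    """Circular mean of angles in degrees, reported in [low, low+360)."""
    deg = np.asarray(deg, dtype=float)
    if deg.size == 0:
        return float("nan")
    z = np.exp(1j * np.deg2rad(deg))
    ang = np.rad2deg(np.angle(np.mean(z)))
    return float((ang - low) % 360.0 + low)
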