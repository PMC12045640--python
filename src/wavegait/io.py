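"""Readers/writers for the point-tracking text dialects the pipeline consumes.

Two dialects are supported:

* a manual-tracking table (one row per tracked point per frame) with
  columns ``track, slice, x, y`` — the layout produced by interactive
  point-tracking plugins; delimiter (comma/tab/whitespace) is autodetected,
* a centroid table with columns ``frame, x, y, angle`` where ``angle`` is
  the per-frame body-bending angle in degrees (180 = straight), the
  convention of whole-larva trackers.

Both readers re-index frames to a 0-based clock and treat any gap or
duplicate as an ingestion error: downstream analyses assume dense,
contiguous sampling.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    LEG_IDS,
    CentroidTrack,
    IngestionError,
    LegTrackTable,
    PlantEventList,
)

_COORD_FMT = "%.6f"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"input file not found: {path}")
    # sep=None lets pandas sniff commas/tabs; fall back to whitespace.
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception:
        df = pd.read_csv(path, sep=r"\s+", engine="python")
    if df.shape[1] == 1:
        df = pd.read_csv(path, sep=r"\s+", engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _find_column(df: pd.DataFrame, keys: Sequence[str], label: str) -> str:
    for col in df.columns:
        name = re.sub(r"[^a-z]", "", col)
        for key in keys:
            if key in name:
                return col
    raise IngestionError(f"required column '{label}' not found in {list(df.columns)}")


def read_manual_track(
    path: str | Path,
    fps: float,
    mm_per_px: float,
    leg_order: Sequence[str] = LEG_IDS,
    animal_id: str | None = None,
) -> LegTrackTable:
    """Read a manual-tracking table into a :class:`LegTrackTable`.

    ``leg_order`` assigns leg identities to track numbers: the i-th entry
    labels the i-th track number in ascending order. Trackers do not store
    which leg a track belongs to, so the caller must supply the mapping.
    """
    leg_order = list(leg_order)
    if sorted(leg_order) != sorted(LEG_IDS):
        raise IngestionError(f"leg_order must be a permutation of {LEG_IDS}")
    df = _read_table(path)
    c_track = _find_column(df, ("track",), "track")
    c_slice = _find_column(df, ("slice", "framen"), "slice")
    c_x = _find_column(df, ("x",), "x")
    c_y = _find_column(df, ("y",), "y")

    tracks = sorted(df[c_track].unique())
    if len(tracks) != 6:
        raise IngestionError(f"expected 6 legs (tracks), found {len(tracks)}")

    legs: dict[str, np.ndarray] = {}
    slice0 = None
    n_ref = None
    for track_no, leg in zip(tracks, leg_order):
        sub = df[df[c_track] == track_no].sort_values(c_slice)
        slices = sub[c_slice].to_numpy(dtype=int)
        if np.unique(slices).size != slices.size:
            dup = int(slices[np.where(np.diff(slices) == 0)[0][0]])
            raise IngestionError(f"duplicate entry at track {track_no} slice {dup}")
        gaps = np.where(np.diff(slices) != 1)[0]
        if gaps.size:
            missing = int(slices[gaps[0]] + 1)
            raise IngestionError(f"gap at track {track_no} slice {missing}")
        if slice0 is None:
            slice0, n_ref = int(slices[0]), slices.size
        elif int(slices[0]) != slice0 or slices.size != n_ref:
            raise IngestionError(
                f"track {track_no} spans slices {slices[0]}..{slices[-1]}, "
                f"expected {slice0}..{slice0 + n_ref - 1}"
            )
        legs[leg] = sub[[c_x, c_y]].to_numpy(dtype=float)

    return LegTrackTable(
        fps=fps,
        mm_per_px=mm_per_px,
        legs=legs,
        animal_id=animal_id or Path(path).stem,
    )


def write_manual_track(table: LegTrackTable, path: str | Path) -> None:
    """Write a :class:`LegTrackTable` in the manual-tracking dialect.

    Track numbers 1..6 follow :data:`wavegait.core.LEG_IDS` order, so a
    round trip with the default ``leg_order`` restores leg identities.
    """
    rows = []
    for track_no, leg in enumerate(LEG_IDS, start=1):
        xy = table.legs[leg]
        for frame in range(xy.shape[0]):
            rows.append((track_no, frame, xy[frame, 0], xy[frame, 1]))
    df = pd.DataFrame(rows, columns=["track", "slice", "x", "y"])
    df.to_csv(path, index=False, float_format=_COORD_FMT)


def read_centroid_track(
    path: str | Path, fps: float, mm_per_px: float, animal_id: str | None = None
) -> CentroidTrack:
    """Read a centroid table (frame, x, y, bending angle) into a track."""
    df = _read_table(path)
    c_frame = _find_column(df, ("frame", "slice", "time"), "frame")
    c_x = _find_column(df, ("x",), "x")
    c_y = _find_column(df, ("y",), "y")
    try:
        c_angle = _find_column(df, ("angle", "bending"), "angle")
    except IngestionError:
        raise IngestionError("required column 'angle' (body bending angle) not found")
    frames = df[c_frame].to_numpy(dtype=int)
    order = np.argsort(frames, kind="stable")
    if not np.array_equal(order, np.arange(frames.size)):
        raise IngestionError("frame column must be monotonically increasing")
    d = np.diff(frames)
    if np.any(d == 0):
        raise IngestionError(f"duplicate frame {int(frames[np.where(d == 0)[0][0]])}")
    if np.any(d != 1):
        raise IngestionError(f"frame gap after frame {int(frames[np.where(d > 1)[0][0]])}")
    return CentroidTrack(
        fps=fps,
        mm_per_px=mm_per_px,
        xy=df[[c_x, c_y]].to_numpy(dtype=float),
        angle_deg=df[c_angle].to_numpy(dtype=float),
        animal_id=animal_id or Path(path).stem,
    )


def write_centroid_track(track: CentroidTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "x": track.xy[:, 0],
            "y": track.xy[:, 1],
            "angle": track.angle_deg,
        }
    )
    df.to_csv(path, index=False, float_format=_COORD_FMT)


def read_events(path: str | Path, fps: float, n_frames: int | None = None) -> PlantEventList:
    """Read a plant-event frame list (one integer frame per line, or a CSV
    with a 'frame' column)."""
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"input file not found: {path}")
    tokens = path.read_text().replace(",", " ").split()
    # a leading header token ('frame', ...) is skipped
    frames = np.array(
        [int(tok) for tok in tokens if not any(c.isalpha() for c in tok)], dtype=int
    )
    return PlantEventList(frames=frames, fps=fps, n_frames=n_frames)


def write_events(events: PlantEventList, path: str | Path) -> None:
    pd.DataFrame({"frame": events.frames}).to_csv(path, index=False)
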