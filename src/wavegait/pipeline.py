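"""Top-level pipeline: one entry point per analysis stage, writing tidy
delimited-text result tables plus a JSON run manifest."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import LEG_IDS, IngestionError, ParameterError, UndefinedResult
from . import io as wio
from . import kinematics as kin
from . import coherence as coh
from . import cycles as cyc
from . import events as ev
from . import path as pb
from .simulate import GaitParams, PathParams, simulate_gait, simulate_path

SUBCOMMANDS = ("simulate", "gait", "coherence", "cycles", "events", "path")


def _write_manifest(out_dir: Path, cfg: RunConfig, inputs: Dict[str, str],
                    subcommand: str, outputs: list[str]) -> None:
    import scipy

    manifest = {
        "subcommand": subcommand,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": outputs,
        "versions": {
            "wavegait": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(
    subcommand: str,
    cfg: RunConfig,
    inputs: Dict[str, str],
    out_dir: str | Path,
    fps: float = 60.0,
    mm_per_px: float = 0.01,
) -> Dict[str, Path]:
    """Run one pipeline stage and write its result tables.

    ``inputs`` maps roles ('legs', 'centroid', 'events') to file paths;
    which roles are required depends on the subcommand. Returns the paths
    of the written outputs. Deterministic given ``cfg.seed``.
    """
    if subcommand not in SUBCOMMANDS:
        raise ParameterError(
            f"unknown subcommand {subcommand!r}; expected one of {SUBCOMMANDS}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        outputs[name] = p

    if subcommand == "simulate":
        gait_params = GaitParams(fps=fps, mm_per_px=mm_per_px, seed=cfg.seed)
        table, truth, events = simulate_gait(gait_params)
        wio.write_manual_track(table, out_dir / "legs.csv")
        outputs["legs"] = out_dir / "legs.csv"
        wio.write_events(events, out_dir / "events.csv")
        outputs["events"] = out_dir / "events.csv"
        truth_rows = [
            {"leg": leg, "start_s": s, "end_s": e}
            for leg in LEG_IDS
            for s, e in truth.swing_times[leg]
        ]
        save("gait_truth", pd.DataFrame(truth_rows))
        path_params = PathParams(seed=cfg.seed)
        ctrack, ptruth = simulate_path(path_params)
        wio.write_centroid_track(ctrack, out_dir / "centroid.csv")
        outputs["centroid"] = out_dir / "centroid.csv"
        save(
            "path_truth",
            pd.DataFrame({"frame": np.arange(ptruth.states.size),
                          "state": ptruth.states,
                          "headsweep": ptruth.headsweep}),
        )
    elif subcommand == "gait":
        track = _require_legs(inputs, fps, mm_per_px)
        vel = kin.leg_speed(track, cfg)
        ss = kin.segment_swings(vel, cfg)
        save("swing_intervals", kin.intervals_frame(ss, track.animal_id))
        summary = kin.summarise(track, cfg)
        save("kinematics_summary", kin.summary_frame(summary))
    elif subcommand == "coherence":
        track = _require_legs(inputs, fps, mm_per_px)
        vel = kin.leg_speed(track, cfg)
        result = coh.leg_coherence(vel, cfg)
        rows = [
            {
                "animal": track.animal_id,
                "leg": leg,
                "magnitude": result.magnitude[leg],
                "phase_deg": result.phase_deg[leg],
                "significant": result.significant[leg],
                "f0_hz": result.f0,
                "threshold": result.threshold,
                "dof": result.dof,
                "anchor": result.anchor,
            }
            for leg in result.magnitude
        ]
        save("coherence", pd.DataFrame(rows))
    elif subcommand == "cycles":
        track = _require_legs(inputs, fps, mm_per_px)
        vel = kin.leg_speed(track, cfg)
        ss = kin.segment_swings(vel, cfg)
        cycles = cyc.extract_t3_to_t1_cycles(ss)
        save("walk_cycles", cyc.cycles_frame(cycles, track.animal_id))
        stances = np.concatenate(list(kin.stance_durations(ss).values()))
        kept, discarded = cyc.filter_pauses(stances)
        frac = cyc.extraction_fraction(cycles, track.duration)
        save(
            "extraction_report",
            pd.DataFrame(
                [
                    {
                        "animal": track.animal_id,
                        "n_cycles": len(cycles),
                        "fraction_pct": frac,
                        "n_stances_discarded": int(discarded.size),
                    }
                ]
            ),
        )
    elif subcommand == "events":
        track = _require_legs(inputs, fps, mm_per_px)
        if "events" not in inputs:
            raise IngestionError("events subcommand requires an 'events' input")
        events = wio.read_events(inputs["events"], fps, n_frames=track.n_frames)
        vel = kin.leg_speed(track, cfg)
        ss = kin.segment_swings(vel, cfg)
        alignment = ev.align_events_to_swings(events, ss)
        save("event_alignment", ev.alignment_frame(alignment, track.animal_id))
        counts, edges = ev.offset_histogram(alignment)
        save(
            "offset_histogram",
            pd.DataFrame({"bin_left_s": edges[:-1], "bin_right_s": edges[1:],
                          "normalised_count": counts}),
        )
        rate = ev.plant_rate(events, track.duration)
        save("plant_rate", pd.DataFrame([{"animal": track.animal_id,
                                          "rate_hz": rate,
                                          "n_events": len(events)}]))
        body_v = np.mean([vel.speed[leg] for leg in LEG_IDS], axis=0)
        try:
            ta = ev.event_triggered_velocity(body_v, fps, events, cfg.event_window_s)
        except (ParameterError, UndefinedResult):
            ta = None   # no event with a full window; table omitted
        if ta is not None:
            save("triggered_average",
                 pd.DataFrame({"lag_s": ta.lags, "normalised_velocity": ta.mean}))
    elif subcommand == "path":
        if "centroid" not in inputs:
            raise IngestionError("path subcommand requires a 'centroid' input")
        ctrack = wio.read_centroid_track(inputs["centroid"], fps, mm_per_px)
        series = pb.classify_states(ctrack)
        save("states", pb.states_frame(series, fps, ctrack.animal_id))
        eps = pb.detect_backtrack_redirect(ctrack)
        save(
            "backtrack_episodes",
            pd.DataFrame(
                [
                    {"animal": ctrack.animal_id, "start_frame": e.start,
                     "end_frame": e.end, "first_turn": e.first_turn,
                     "backtrack_mm": e.backtrack_mm}
                    for e in eps
                ]
            ),
        )
        v = pb.instantaneous_velocity(ctrack)
        sweeps = pb.headsweep_episodes(series)
        n_left = sum(1 for _, _, s in sweeps if s == "left")
        n_right = sum(1 for _, _, s in sweeps if s == "right")
        props = series.proportions()
        try:
            curv = pb.curviness(ctrack)
        except Exception:
            curv = float("nan")
        save(
            "path_summary",
            pd.DataFrame(
                [
                    {
                        "animal": ctrack.animal_id,
                        "mean_velocity_mm_s": float(np.mean(v)),
                        "total_distance_mm": pb.total_distance(ctrack),
                        "curviness": curv,
                        "pct_straight": 100 * props["straight"],
                        "pct_bent": 100 * props["bent"],
                        "pct_still": 100 * props["still"],
                        "n_left_headsweeps": n_left,
                        "n_right_headsweeps": n_right,
                        "n_backtrack_episodes": len(eps),
                    }
                ]
            ),
        )

    _write_manifest(out_dir, cfg, inputs, subcommand,
                    [str(p) for p in outputs.values()])
    return outputs


def _require_legs(inputs: Dict[str, str], fps: float, mm_per_px: float):
    if "legs" not in inputs:
        raise IngestionError("this subcommand requires a 'legs' input")
    return wio.read_manual_track(inputs["legs"], fps, mm_per_px)
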