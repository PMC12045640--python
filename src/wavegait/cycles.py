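"""Walk-cycle extraction and pause filtering.

A walk cycle follows the posterior-to-anterior sequence: both metathoracic
(T3) legs swing, then both mesothoracic (T2), then both prothoracic (T1),
all before the next T3 onset. Within a segment the left/right order is
unconstrained (bilateral synchrony). Pause periods are removed by
discarding stance durations longer than the animal's median + 1 s.d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core import LEG_IDS, ParameterError
from .kinematics import SwingStanceSeries

__all__ = [
    "WalkCycle",
    "ExtractionReport",
    "extract_t3_to_t1_cycles",
    "filter_pauses",
    "extraction_fraction",
]


@dataclass
class WalkCycle:
    """One extracted T3->T1 cycle: the six onset times and its span."""

    onsets: Dict[str, float]   # leg id -> onset time, s
    start: float               # first T3 onset, s
    end: float                 # next cycle's first T3 onset, s

    @property
    def period(self) -> float:
        return self.end - self.start


@dataclass
class ExtractionReport:
    n_cycles: int
    fraction_pct: float          # % of total tracked time inside cycles
    n_stances_discarded: int


def _first_at_or_after(times: np.ndarray, t: float) -> float | None:
    idx = np.searchsorted(times, t)
    return float(times[idx]) if idx < times.size else None


def extract_t3_to_t1_cycles(ss: SwingStanceSeries) -> List[WalkCycle]:
    """Greedy left-to-right extraction of T3->T1 walk cycles.

    A candidate starts at a T3 onset (either side). It is accepted iff the
    contralateral T3 onset and then both T2 and both T1 onsets occur, in
    segment order, before the following T3 onset; the cycle span is
    ``[first T3 onset, next cycle's first T3 onset)``. Candidates at the
    end of the record that cannot be closed by a following T3 onset are
    dropped.
    """
    onsets = {leg: ss.onset_times(leg) for leg in LEG_IDS}
    t3_merged = sorted(
        [(t, leg) for leg in ("T3L", "T3R") for t in onsets[leg]]
    )
    cycles: List[WalkCycle] = []
    i = 0
    while i < len(t3_merged):
        t3a, leg_a = t3_merged[i]
        other = "T3R" if leg_a == "T3L" else "T3L"
        t3b = _first_at_or_after(onsets[other], t3a)
        if t3b is None:
            break
        t3_hi = max(t3a, t3b)
        # next T3 onset of either side strictly after the pair
        later = [t for t, _ in t3_merged if t > t3_hi]
        t_end = later[0] if later else None

        t2l = _first_at_or_after(onsets["T2L"], t3_hi)
        t2r = _first_at_or_after(onsets["T2R"], t3_hi)
        ok = t2l is not None and t2r is not None
        if ok:
            t2_hi = max(t2l, t2r)
            t1l = _first_at_or_after(onsets["T1L"], t2_hi)
            t1r = _first_at_or_after(onsets["T1R"], t2_hi)
            ok = t1l is not None and t1r is not None
        if ok and t_end is not None and max(t1l, t1r) < t_end:
            cycles.append(
                WalkCycle(
                    onsets={
                        "T3L": t3a if leg_a == "T3L" else t3b,
                        "T3R": t3a if leg_a == "T3R" else t3b,
                        "T2L": t2l,
                        "T2R": t2r,
                        "T1L": t1l,
                        "T1R": t1r,
                    },
                    start=t3a,
                    end=t_end,
                )
            )
            # resume scanning at the closing T3 onset
            while i < len(t3_merged) and t3_merged[i][0] < t_end:
                i += 1
        else:
            i += 1
    return cycles


def filter_pauses(stances: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split stance durations into (kept, discarded-as-pause).

    Stances longer than median + 1 sample s.d. of the input distribution
    are treated as pauses. With all stances equal (sd = 0) nothing is
    discarded.
    """
    stances = np.asarray(stances, dtype=float)
    if stances.size == 0:
        return stances, stances
    med = float(np.median(stances))
    sd = float(np.std(stances, ddof=1)) if stances.size > 1 else 0.0
    cut = med + sd
    keep = stances <= cut
    return stances[keep], stances[~keep]


def extraction_fraction(cycles: List[WalkCycle], total_time: float) -> float:
    """Percent of the tracked record covered by extracted cycles."""
    if total_time <= 0:
        raise ParameterError("total_time must be > 0")
    covered = sum(c.period for c in cycles)
    return 100.0 * covered / total_time


def cycles_frame(cycles: List[WalkCycle], animal_id: str = "animal") -> pd.DataFrame:
    rows = []
    for k, c in enumerate(cycles):
        row = {"animal": animal_id, "cycle_idx": k, "start_s": c.start,
               "end_s": c.end, "period_s": c.period}
        row.update({f"onset_{leg}_s": c.onsets[leg] for leg in LEG_IDS})
        rows.append(row)
    return pd.DataFrame(rows)
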