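import numpy as np
import pytest

from wavegait import GaitParams, RunConfig, simulate_gait
from wavegait import kinematics as kin


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def fast_gait():
    """One clean fast-walking simulation (defaults, seed 1) with its
    velocity series and swing segmentation."""
    table, truth, events = simulate_gait(GaitParams(seed=1))
    vel = kin.leg_speed(table)
    ss = kin.segment_swings(vel)
    return {"table": table, "truth": truth, "events": events, "vel": vel, "ss": ss}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_velocity_series(pulses, n, fps=60.0, amplitude=8.0):
    """VelocitySeries with square speed pulses at given [start, end) frames
    on all six legs (used to test segmentation against a threshold oracle
    without smoothing effects)."""
    from wavegait.core import LEG_IDS

    v = np.zeros(n)
    for s, e in pulses:
        v[s:e] = amplitude
    return kin.VelocitySeries(
        speed={leg: v.copy() for leg in LEG_IDS}, fps=fps, sg_window=5, sg_order=2
    )
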