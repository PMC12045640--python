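"""Run configuration: every tunable of the analysis chain in one place.

A :class:`RunConfig` can be loaded from a plain ``key = value`` text file
(``#`` comments allowed) so that a whole run is reproducible from the file
plus the seed recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .core import ParameterError


@dataclass
class RunConfig:
    """Analysis settings.

    Parameters
    ----------
    sg_window : int or None
        Savitzky-Golay smoothing window in frames (odd). ``None`` selects
        ``max(5, odd(round(0.05 s * fps)))``, wide enough to suppress
        tracking jitter while passing stepping at ~5 Hz.
    sg_order : int
        Savitzky-Golay polynomial order.
    swing_threshold_frac : float
        Entry threshold for swing detection as a fraction of the per-leg
        robust peak speed (95th percentile). The exit threshold of the
        hysteresis is half the entry threshold.
    min_swing_s : float or None
        Minimum swing duration; shorter supra-threshold runs are discarded.
        ``None`` selects two frames at the data's frame rate.
    plateau_tol : float
        Relative tolerance defining a spectral plateau: bins with power
        >= (1 - plateau_tol) * max count as part of the peak plateau.
    alpha : float
        Significance level of the coherence threshold.
    n_tapers : int
        Number of DPSS tapers (K).
    n_observations : int or None
        Number of non-overlapping segments (R) averaged in the multitaper
        estimate. ``None`` selects one segment per second of data.
    time_bandwidth : float
        DPSS time-bandwidth product NW; must satisfy K <= 2*NW - 1.
    taper : str
        'dpss' (default) or 'boxcar' (single rectangular window, K must
        be 1; mainly for cross-checks against plain periodogram averaging).
    event_window_s : float
        Half-width of the event-triggered-average window, seconds.
    histogram_rule : str
        Bin-width rule for event-offset histograms ('freedman-diaconis').
    seed : int
        Seed recorded in the run manifest and used by simulation commands.
    """

    sg_window: int | None = None
    sg_order: int = 2
    swing_threshold_frac: float = 0.3
    min_swing_s: float | None = None
    plateau_tol: float = 0.05
    alpha: float = 0.05
    n_tapers: int = 7
    n_observations: int | None = None
    time_bandwidth: float = 4.0
    taper: str = "dpss"
    event_window_s: float = 1.0
    histogram_rule: str = "freedman-diaconis"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_tapers < 1:
            raise ParameterError("n_tapers (K) must be >= 1")
        if self.n_observations is not None and self.n_observations < 1:
            raise ParameterError("n_observations (R) must be >= 1")
        if self.sg_window is not None:
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
                raise ParameterError("sg_window must be odd and > sg_order")
        if not (0.0 < self.swing_threshold_frac <= 1.0):
            raise ParameterError("swing_threshold_frac must be in (0, 1]")
        if self.taper not in ("dpss", "boxcar"):
            raise ParameterError("taper must be 'dpss' or 'boxcar'")
        if self.taper == "boxcar" and self.n_tapers != 1:
            raise ParameterError("boxcar taper requires n_tapers == 1")
        if self.plateau_tol < 0 or self.plateau_tol >= 1:
            raise ParameterError("plateau_tol must be in [0, 1)")

    # --- derived defaults -------------------------------------------------

    def resolve_sg_window(self, fps: float) -> int:
        if self.sg_window is not None:
            return self.sg_window
        w = int(round(0.05 * fps))
        if w % 2 == 0:
            w += 1
        return max(5, w)

    def resolve_min_swing_frames(self, fps: float) -> int:
        if self.min_swing_s is None:
            return 2
        return max(1, int(round(self.min_swing_s * fps)))

    def resolve_n_observations(self, n_samples: int, fps: float) -> int:
        if self.n_observations is not None:
            return self.n_observations
        return max(1, int(n_samples / fps))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _coerce(name: str, raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    if name in ("taper", "histogram_rule"):
        return raw
    if name in ("sg_window", "sg_order", "n_tapers", "n_observations", "seed"):
        return int(raw)
    return float(raw)


def load_config(path: str | Path) -> RunConfig:
    """Read a ``key = value`` config file into a :class:`RunConfig`."""
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise IngestionErrorForConfig(path, lineno, line)
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise ParameterError(f"{path}: unknown config key '{key}' (line {lineno})")
        kwargs[key] = _coerce(key, value)
    return RunConfig(**kwargs)


def IngestionErrorForConfig(path, lineno, line):
    return ParameterError(f"{path}: expected 'key = value' on line {lineno}: {line!r}")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
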