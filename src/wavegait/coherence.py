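"""Spectral analysis: fundamental frequency and multitaper coherence.

The anchor leg's stepping frequency is taken from the power spectrum of
its speed trace (highest-power bin, with plateau tie rules). The other
legs are then compared against the anchor by DPSS-multitaper coherence,
averaging cross- and auto-spectra over K tapers and R non-overlapping
segments. With degrees of freedom dof = 2RK, the magnitude threshold for
significant coherence at level alpha is

    threshold = sqrt(1 - alpha**(1 / (dof/2 - 1)))

which is the exact null quantile for the magnitude-squared coherence of
independent Gaussian signals estimated from dof/2 independent
taper-segment products.

Phase convention: the reported phase is the argument of the averaged
cross-spectrum conj(X)*Y in degrees, so a signal that is a pure delay of
the anchor has negative phase at the stepping frequency (negative =
temporally later here reported against the anchor; a quarter-period delay
gives -90 deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.signal.windows import dpss

from .config import RunConfig
from .core import (
    LEG_IDS,
    ParameterError,
    UndefinedResult,
    wrap_deg_180,
)
from .kinematics import VelocitySeries

__all__ = [
    "SpectralResult",
    "CoherenceResult",
    "power_spectrum",
    "fundamental_frequency",
    "multitaper_coherence",
    "coherence_threshold",
    "leg_coherence",
    "coherent_leg_fraction",
]


@dataclass
class SpectralResult:
    """One-sided power spectrum of a speed trace."""

    freqs: np.ndarray   # Hz, increasing
    power: np.ndarray   # >= 0
    df: float           # frequency resolution, Hz


def power_spectrum(x: np.ndarray, fps: float) -> SpectralResult:
    """Periodogram of a (mean-removed) trace; one-sided."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ParameterError("trace too short for a spectrum (need >= 8 samples)")
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / x.size
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
    return SpectralResult(freqs=freqs, power=spec, df=float(freqs[1] - freqs[0]))


def fundamental_frequency(
    x: np.ndarray | SpectralResult, fps: float | None = None, plateau_tol: float = 0.05
) -> float:
    """Stepping (fundamental) frequency of a speed trace.

    Returns the frequency of greatest power density, excluding the DC bin.
    Near-ties are resolved by plateau rules: bins within ``plateau_tol``
    (relative) of the maximum form plateaus; the middle bin of the peak
    plateau is returned, and with exactly two plateaus the
    higher-frequency one is used.
    """
    if isinstance(x, SpectralResult):
        spec = x
    else:
        if fps is None:
            raise ParameterError("fps required when passing a raw trace")
        spec = power_spectrum(x, fps)
    p = spec.power[1:]          # DC excluded
    f = spec.freqs[1:]
    pmax = float(np.max(p)) if p.size else 0.0
    if pmax <= 0.0:
        raise UndefinedResult("flat zero spectrum: fundamental frequency undefined")
    mask = p >= (1.0 - plateau_tol) * pmax
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < mask.size:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < mask.size and mask[j]:
            j += 1
        runs.append((i, j))
        i = j
    if len(runs) == 1:
        s, e = runs[0]
    elif len(runs) == 2:
        s, e = runs[1]                      # higher-frequency block
    else:
        k = int(np.argmax(p))               # block containing the global max
        s, e = next((a, b) for a, b in runs if a <= k < b)
    mid = s + (e - s - 1) // 2
    return float(f[mid])


def coherence_threshold(alpha: float, dof: int) -> float:
    """Minimum coherence magnitude that is significant at level ``alpha``.

    ``dof = 2RK`` must exceed 2. The threshold decreases monotonically in
    dof: more independent averages make small coherences detectable.
    """
    if dof <= 2:
        raise ParameterError("dof = 2RK must be > 2")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    n = dof / 2.0
    return float(np.sqrt(1.0 - alpha ** (1.0 / (n - 1.0))))


def _tapers(L: int, cfg: RunConfig) -> np.ndarray:
    K = cfg.n_tapers
    if cfg.taper == "boxcar":
        return np.ones((1, L)) / np.sqrt(L)
    if K > 2 * cfg.time_bandwidth - 1:
        raise ParameterError(
            f"K={K} tapers infeasible for time-bandwidth NW={cfg.time_bandwidth}; "
            "need K <= 2*NW - 1"
        )
    w = dpss(L, cfg.time_bandwidth, Kmax=K)
    return np.atleast_2d(w)


def _coherence_spectra(
    x: np.ndarray, y: np.ndarray, fps: float, cfg: RunConfig, R: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency grid, coherence magnitude and phase (deg) across bins."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("signals must have equal length")
    L = x.size // R
    if L < 8:
        raise ParameterError(
            f"segments of {L} samples are too short; use fewer observations "
            f"(R={R}) or longer traces"
        )
    segs_x = x[: R * L].reshape(R, L)
    segs_y = y[: R * L].reshape(R, L)
    segs_x = segs_x - segs_x.mean(axis=1, keepdims=True)
    segs_y = segs_y - segs_y.mean(axis=1, keepdims=True)
    W = _tapers(L, cfg)                                   # (K, L)
    X = np.fft.rfft(segs_x[:, None, :] * W[None, :, :], axis=-1)   # (R, K, F)
    Y = np.fft.rfft(segs_y[:, None, :] * W[None, :, :], axis=-1)
    Sxy = np.sum(np.conj(X) * Y, axis=(0, 1))
    Sxx = np.sum(np.abs(X) ** 2, axis=(0, 1))
    Syy = np.sum(np.abs(Y) ** 2, axis=(0, 1))
    denom = np.sqrt(Sxx * Syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(Sxy) / denom, 0.0)
    phase = np.rad2deg(np.angle(Sxy))
    freqs = np.fft.rfftfreq(L, d=1.0 / fps)
    return freqs, coh, phase


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    f0: float,
    cfg: RunConfig | None = None,
    n_observations: int | None = None,
) -> Tuple[float, float]:
    """Coherence magnitude and phase (deg) of ``y`` against ``x`` at the
    frequency bin nearest ``f0``.

    Magnitude is in [0, 1] (Cauchy-Schwarz) and invariant to amplitude
    scaling of either signal; phase is antisymmetric under exchanging the
    signals.
    """
    cfg = cfg or RunConfig()
    R = n_observations if n_observations is not None else cfg.resolve_n_observations(
        np.asarray(x).size, fps
    )
    freqs, coh, phase = _coherence_spectra(x, y, fps, cfg, R)
    k = int(np.argmin(np.abs(freqs - f0)))
    return float(coh[k]), float(wrap_deg_180(phase[k]))


@dataclass
class CoherenceResult:
    """Coherence of the five non-anchor legs against the anchor leg."""

    anchor: str
    f0: float
    magnitude: Dict[str, float]
    phase_deg: Dict[str, float]
    threshold: float
    significant: Dict[str, bool]
    dof: int


def leg_coherence(
    vel: VelocitySeries, cfg: RunConfig | None = None, anchor: str = "T1L"
) -> CoherenceResult:
    """Full coherence analysis of one animal against an anchor leg."""
    cfg = cfg or RunConfig()
    if anchor not in LEG_IDS:
        raise ParameterError(f"unknown anchor leg {anchor!r}")
    f0 = fundamental_frequency(vel.speed[anchor], vel.fps, cfg.plateau_tol)
    R = cfg.resolve_n_observations(vel.n_samples, vel.fps)
    dof = 2 * R * cfg.n_tapers
    thr = coherence_threshold(cfg.alpha, dof)
    magnitude: Dict[str, float] = {}
    phase: Dict[str, float] = {}
    significant: Dict[str, bool] = {}
    for leg in LEG_IDS:
        if leg == anchor:
            continue
        mag, ph = multitaper_coherence(
            vel.speed[anchor], vel.speed[leg], vel.fps, f0, cfg, n_observations=R
        )
        magnitude[leg] = mag
        phase[leg] = ph
        significant[leg] = mag >= thr
    return CoherenceResult(
        anchor=anchor,
        f0=f0,
        magnitude=magnitude,
        phase_deg=phase,
        threshold=thr,
        significant=significant,
        dof=dof,
    )


def coherent_leg_fraction(result: CoherenceResult) -> float:
    """Percentage of the five non-anchor legs significantly coherent with
    the anchor."""
    flags = list(result.significant.values())
    if len(flags) != 5:
        raise ParameterError("expected five non-anchor legs")
    return 100.0 * sum(flags) / 5.0
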