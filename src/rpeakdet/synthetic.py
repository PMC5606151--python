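"""Synthetic single-channel ECG with exact R-peak ground truth.

Each beat is a sum of five Gaussians (P, Q, R, S, T) placed at RR-jittered
onsets; on top of the beat train the generator can add baseline drift,
powerline interference and broadband Gaussian noise.  A configurable
fraction of beats is made PVC-like (R negated and widened, T enlarged) or
small-amplitude (R scaled down), reproducing the morphologies that challenge
amplitude/time-interval thresholding: negative R-peaks, large T waves, mixed
large and small R amplitudes, and baseline wander.

The model is deliberately analytic rather than physiological — wave
amplitudes and widths are exact inputs, so threshold behaviour can be
verified against constructed truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BeatAnnotations, EcgRecord

__all__ = ["WaveParam", "SynthConfig", "generate", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class WaveParam:
    """One Gaussian deflection: amplitude (mV), centre offset from the
    R-peak (s), and Gaussian width sigma (s)."""

    amplitude: float
    offset_s: float
    width_s: float

    def __post_init__(self) -> None:
        if not self.width_s > 0:
            raise ValueError("wave width must be positive")


#: Default beat morphology.  R/T amplitude ratio ~4.3, P and T widths much
#: larger than the QRS deflections, all within common clinical ranges.
DEFAULT_WAVES: dict[str, WaveParam] = {
    "P": WaveParam(0.15, -0.20, 0.025),
    "Q": WaveParam(-0.10, -0.035, 0.010),
    "R": WaveParam(1.00, 0.0, 0.012),
    "S": WaveParam(-0.15, 0.035, 0.010),
    "T": WaveParam(0.23, 0.25, 0.060),
}

#: Physiological floor on the RR interval (s); enforced by construction.
MIN_RR_S = 0.3


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 360.0
    duration_s: float = 120.0
    rr_mean_s: float = 0.8
    rr_sd_s: float = 0.0
    wave_params: dict[str, WaveParam] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    pvc_fraction: float = 0.0
    small_r_fraction: float = 0.0
    small_r_scale: float = 0.35
    drift_amplitude_mv: float = 0.0
    drift_frequency_hz: float = 0.25
    noise_sd_mv: float = 0.0
    powerline_amplitude_mv: float = 0.0
    powerline_frequency_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.rr_mean_s > 0:
            raise ValueError("rr_mean_s must be positive")
        if self.rr_sd_s < 0:
            raise ValueError("rr_sd_s must be non-negative")
        for frac in (self.pvc_fraction, self.small_r_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("beat-type fractions must lie in [0, 1]")


def generate(cfg: SynthConfig, record_id: str = "synthetic") -> tuple[EcgRecord, BeatAnnotations]:
    """Generate an ECG record with exact R-centre annotations.

    Deterministic under a fixed ``cfg.seed``; all randomness (RR jitter,
    beat-type assignment, noise) flows through one seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    L = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(L) / cfg.fs

    # R-peak centre times: jittered RR increments with a physiological floor,
    # leaving a small margin at the end of the record.
    centers: list[float] = []
    c = cfg.rr_mean_s / 2
    margin = cfg.duration_s - 0.25
    while c <= margin:
        centers.append(c)
        rr = cfg.rr_mean_s
        if cfg.rr_sd_s > 0:
            rr = rng.normal(cfg.rr_mean_s, cfg.rr_sd_s)
        c += max(MIN_RR_S, rr)
    n_beats = len(centers)

    # Beat types: PVCs first, small-R beats among the remainder.
    u = rng.random(n_beats)
    is_pvc = u < cfg.pvc_fraction
    is_small = (~is_pvc) & (rng.random(n_beats) < cfg.small_r_fraction)

    x = np.zeros(L)
    for c, pvc, small in zip(centers, is_pvc, is_small):
        waves = dict(cfg.wave_params)
        if pvc:
            r = waves["R"]
            waves["R"] = replace(r, amplitude=-r.amplitude, width_s=2 * r.width_s)
            tw = waves["T"]
            waves["T"] = replace(tw, amplitude=1.5 * tw.amplitude)
        elif small:
            r = waves["R"]
            waves["R"] = replace(r, amplitude=cfg.small_r_scale * r.amplitude)
        for w in waves.values():
            center = c + w.offset_s
            lo = max(0, int((center - 5 * w.width_s) * cfg.fs))
            hi = min(L, int((center + 5 * w.width_s) * cfg.fs) + 1)
            if hi > lo:
                x[lo:hi] += w.amplitude * np.exp(
                    -0.5 * ((t[lo:hi] - center) / w.width_s) ** 2
                )

    if cfg.drift_amplitude_mv:
        x += cfg.drift_amplitude_mv * np.sin(2 * np.pi * cfg.drift_frequency_hz * t)
    if cfg.powerline_amplitude_mv:
        x += cfg.powerline_amplitude_mv * np.sin(2 * np.pi * cfg.powerline_frequency_hz * t)
    if cfg.noise_sd_mv:
        x += rng.normal(0.0, cfg.noise_sd_mv, L)

    indices = np.asarray([int(round(c * cfg.fs)) for c in centers], dtype=np.int64)
    labels = tuple("V" if pvc else "N" for pvc in is_pvc)
    return EcgRecord(record_id, x, cfg.fs), BeatAnnotations(indices, labels)


_PRESETS: dict[str, SynthConfig] = {
    # 150 perfectly periodic beats at 75 bpm with light broadband noise.
    "clean": SynthConfig(noise_sd_mv=0.02, seed=101),
    # 60 beats, 30% PVC-like with inverted widened R; light RR jitter.
    "pvc": SynthConfig(duration_s=48.0, rr_sd_s=0.02, pvc_fraction=0.3,
                       noise_sd_mv=0.02, seed=202),
    # Pronounced sub-Hz baseline wander on an otherwise clean rhythm.
    "drift": SynthConfig(drift_amplitude_mv=0.5, drift_frequency_hz=0.25,
                         noise_sd_mv=0.02, seed=303),
    # T amplitude raised to half the R amplitude: T waves clear a_t at the
    # default K_amp and must be rejected by the time-interval arbitration.
    "large_t": SynthConfig(
        wave_params={**DEFAULT_WAVES, "T": replace(DEFAULT_WAVES["T"], amplitude=0.5)},
        noise_sd_mv=0.02, seed=404),
    # Alternating full-scale and 0.35-scale R-peaks: the amplitude threshold
    # set by the large beats sits just below the small ones.
    "mixed_amplitude": SynthConfig(small_r_fraction=0.5, rr_sd_s=0.02,
                                   noise_sd_mv=0.02, seed=505),
    # Broadband noise plus powerline interference.
    "noisy": SynthConfig(noise_sd_mv=0.10, powerline_amplitude_mv=0.05,
                         rr_sd_s=0.02, seed=606),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> SynthConfig:
    """Named fixture configuration with a fixed seed."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        ) from None
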