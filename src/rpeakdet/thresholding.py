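"""Adaptive amplitude / time-interval thresholding and the full detector.

The enhanced, mirrored signal is processed in contiguous segments (10 s by
default).  Within each segment two thresholds adapt to the local signal:

    a_t  = K_amp  * MAX_seg_amp      (amplitude threshold, mV)
    ti_t = K_time * AVE_max_dis      (time-interval threshold, samples)

where MAX_seg_amp is the largest amplitude in the segment and AVE_max_dis the
mean spacing of the candidates that survive the amplitude threshold.  Local
maxima below a_t are discarded; the survivors are then arbitrated pairwise:
two candidates closer than ti_t cannot both be R-peaks, and the one with the
narrower baseline width (or, on a width tie, the larger amplitude) wins.  No
search-back over missed beats is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EcgRecord, RPeakSet
from .mirror import CandidateSet, MirrorConfig, local_maxima, mirror
from .wmra import enhance

__all__ = [
    "ThresholdParams",
    "SegmentThresholds",
    "PeakMeasure",
    "segment_thresholds",
    "amplitude_filter",
    "peak_width",
    "recognize",
    "detect",
    "DetectionResult",
    "run_detector",
]

#: Average RR interval (s) used to bootstrap ti_t when a segment has no
#: usable candidates; covers the common heart-rate range 0.54-1.19 s.
BOOTSTRAP_RR_S = 0.82


@dataclass(frozen=True)
class ThresholdParams:
    """Dimensionless threshold coefficients and the segment length."""

    k_amp: float = 0.25
    k_time: float = 0.45
    segment_s: float = 10.0
    width_cap_s: float = 0.278

    def __post_init__(self) -> None:
        if not 0 < self.k_amp < 1:
            raise ValueError("k_amp must be in (0, 1)")
        if not 0 < self.k_time < 1:
            raise ValueError("k_time must be in (0, 1)")
        if not self.segment_s > 0:
            raise ValueError("segment_s must be positive")


@dataclass(frozen=True)
class SegmentThresholds:
    """Per-segment thresholds together with the statistics that drove them."""

    a_t: float  # mV
    ti_t: float  # samples
    max_seg_amp: float  # mV
    ave_max_dis: float  # samples
    segment_range: tuple[int, int]
    bootstrapped: bool = False


@dataclass(frozen=True)
class PeakMeasure:
    """Width and amplitude of one candidate, used in arbitration."""

    index: int
    amplitude: float
    width: int


def segment_thresholds(
    candidates: CandidateSet,
    signal: np.ndarray,
    seg: tuple[int, int],
    params: ThresholdParams,
    fs: float,
    prev_ti_t: float | None = None,
) -> SegmentThresholds:
    """Adaptive thresholds for one segment.

    AVE_max_dis is measured over the candidates that survive the amplitude
    threshold — raw maxima include noise ripples whose spacing says nothing
    about the RR interval.  A segment with fewer than two survivors inherits
    the previous segment's ti_t, or bootstraps it from a nominal 0.82 s RR.
    """
    start, end = seg
    window = signal[start:end]
    max_seg_amp = float(window.max(initial=0.0))
    max_seg_amp = max(max_seg_amp, 0.0)
    a_t = params.k_amp * max_seg_amp

    in_seg = (candidates.indices >= start) & (candidates.indices < end)
    survivors = amplitude_filter(candidates.subset(in_seg), a_t)
    if len(survivors) >= 2:
        ave_max_dis = float(np.mean(np.diff(survivors.indices)))
        return SegmentThresholds(a_t, params.k_time * ave_max_dis, max_seg_amp,
                                 ave_max_dis, seg)
    ti_t = prev_ti_t if prev_ti_t is not None else params.k_time * BOOTSTRAP_RR_S * fs
    return SegmentThresholds(a_t, ti_t, max_seg_amp, ti_t / params.k_time, seg,
                             bootstrapped=True)


def amplitude_filter(candidates: CandidateSet, a_t: float) -> CandidateSet:
    """Retain exactly the candidates with amplitude strictly above a_t."""
    if a_t < 0:
        raise ValueError("a_t must be non-negative")
    return candidates.subset(candidates.amplitudes > a_t)


def peak_width(
    signal: np.ndarray,
    index: int,
    fs: float,
    cap_s: float = 0.278,
    rel_level: float = 0.05,
) -> int:
    """Width of a positive peak along the baseline, in samples.

    The width is the distance between the nearest baseline returns on either
    side of the peak: the first sample at or below
    ``max(0, rel_level * peak_amplitude)``, a level just above the zero
    baseline so that peaks riding on a small positive noise floor (or a
    mirrored run bracketed by positive tails) still terminate.  Each side is
    searched at most ``round(cap_s * fs)`` samples; a side without a return
    inside the cap contributes the cap.  Narrow QRS spikes fall back to
    baseline quickly while T and P waves do not, which is what the
    arbitration step exploits.
    """
    x = np.asarray(signal, dtype=float)
    if not x[index] > 0:
        raise ValueError("peak_width requires a positive sample at index")
    cap = int(round(cap_s * fs))
    level = max(0.0, rel_level * x[index])
    left = cap
    for i in range(index - 1, max(-1, index - cap - 1), -1):
        if x[i] <= level:
            left = index - i
            break
    right = cap
    for i in range(index + 1, min(x.size, index + cap + 1)):
        if x[i] <= level:
            right = i - index
            break
    return left + right


def recognize(
    candidates: CandidateSet,
    ti_t: float,
    signal: np.ndarray,
    fs: float,
    width_cap_s: float = 0.278,
    prev_index: int | None = None,
) -> list[int]:
    """Arbitrate amplitude-surviving candidates by the time-interval rule.

    Consecutive candidates form (Tref, Cref) pairs.  A pair separated by at
    least ti_t accepts Tref and promotes Cref to the new reference.  A closer
    pair contains a false peak: the candidate with the smaller baseline width
    survives; on a width tie the larger amplitude survives, and an exact
    amplitude tie resolves to Cref.  The winner keeps the reference role and
    the next candidate becomes the new Cref.  A final lone reference is
    accepted.  ``prev_index``, the last accepted peak of the previous
    segment, suppresses leading candidates closer than ti_t to it.
    """
    idx = [int(i) for i in candidates.indices]
    if prev_index is not None:
        while idx and idx[0] - prev_index < ti_t:
            idx.pop(0)
    if not idx:
        return []

    def measure(i: int) -> PeakMeasure:
        return PeakMeasure(i, float(signal[i]), peak_width(signal, i, fs, width_cap_s))

    accepted: list[int] = []
    tref = measure(idx[0])
    j = 1
    while j < len(idx):
        cref = measure(idx[j])
        t_p = cref.index - tref.index
        if t_p >= ti_t:
            accepted.append(tref.index)
            tref = cref
        else:
            if cref.width < tref.width:
                tref = cref
            elif cref.width == tref.width:
                if not tref.amplitude > cref.amplitude:  # exact tie -> Cref
                    tref = cref
            # else Tref keeps the reference role; Cref is discarded
        j += 1
    accepted.append(tref.index)
    return accepted


@dataclass(frozen=True)
class DetectionResult:
    """Detected R-peaks plus the per-segment thresholds that produced them."""

    peaks: RPeakSet
    segments: tuple[SegmentThresholds, ...]
    mirrored_runs: tuple[tuple[int, int], ...]


def run_detector(
    rec: EcgRecord,
    params: ThresholdParams | None = None,
    mirror_cfg: MirrorConfig | None = None,
    wavelet_name: str = "bior6.8",
    levels: int = 8,
    shrinkage: str = "universal",
    keep_bands: set[str] | None = None,
) -> DetectionResult:
    """Full pipeline with per-segment diagnostics.

    Enhancement -> mirroring -> local maxima -> per-segment amplitude filter
    and time-interval arbitration.  Returned indices refer to the original
    sample grid (the transform is length-preserving).
    """
    params = params or ThresholdParams()
    mirror_cfg = mirror_cfg or MirrorConfig()

    enhanced = enhance(rec, wavelet_name, levels, shrinkage, keep_bands)
    mirrored = mirror(enhanced.samples, rec.fs, mirror_cfg)
    sig = mirrored.samples
    try:
        cands = local_maxima(sig)
    except ValueError:
        cands = CandidateSet(np.empty(0, dtype=np.int64), np.empty(0))

    seg_len = int(round(params.segment_s * rec.fs))
    L = sig.size
    accepted: list[int] = []
    seg_infos: list[SegmentThresholds] = []
    prev_ti_t: float | None = None
    for start in range(0, L, seg_len):
        end = min(start + seg_len, L)
        th = segment_thresholds(cands, sig, (start, end), params, rec.fs, prev_ti_t)
        seg_infos.append(th)
        prev_ti_t = th.ti_t
        in_seg = (cands.indices >= start) & (cands.indices < end)
        survivors = amplitude_filter(cands.subset(in_seg), th.a_t)
        prev_peak = accepted[-1] if accepted else None
        accepted += recognize(survivors, th.ti_t, sig, rec.fs,
                              params.width_cap_s, prev_peak)
    return DetectionResult(
        RPeakSet(np.asarray(accepted, dtype=np.int64)),
        tuple(seg_infos),
        mirrored.mirrored_runs,
    )


def detect(
    rec: EcgRecord,
    params: ThresholdParams | None = None,
    mirror_cfg: MirrorConfig | None = None,
    **kwargs,
) -> RPeakSet:
    """Detect R-peaks in a single-channel ECG record."""
    return run_detector(rec, params, mirror_cfg, **kwargs).peaks
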