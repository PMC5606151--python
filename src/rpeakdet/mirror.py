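"""Signal mirroring for negative R-peaks and sign-of-difference local maxima.

Ectopic beats such as PVCs can carry their R-peak *below* the baseline.  To
avoid missing them, a large negative deflection whose magnitude dominates its
neighbourhood is reflected about the baseline (taken as 0 after wavelet
enhancement), turning it into a positive peak the downstream thresholding can
see.  Local maxima are then located from the sign of the first-order forward
difference: positions where the sign sequence steps from +1 to -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MirrorConfig", "MirroredSignal", "CandidateSet", "mirror", "local_maxima"]


@dataclass(frozen=True)
class MirrorConfig:
    """Mirroring rule parameters.

    A negative local minimum at sample k is reflected when its magnitude is at
    least ``amplitude_multiple`` times the magnitude of every comparison
    sample within ``window_s`` seconds on either side.  The comparison set
    excludes the contiguous negative run containing k itself (the flanks of a
    sharp spike are nearly as deep as its tip, so comparing against them would
    veto every sampled waveform); set ``exclude_own_run=False`` for the
    strictly pointwise rule.  ``scope`` chooses whether the whole negative run
    is reflected (``"run"``, so the mirrored wave keeps its shape) or only the
    single sample (``"point"``).
    """

    amplitude_multiple: float = 1.5
    window_s: float = 0.278
    scope: str = "run"
    exclude_own_run: bool = True
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.amplitude_multiple > 1:
            raise ValueError("amplitude_multiple must exceed 1")
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if self.scope not in ("run", "point"):
            raise ValueError(f"scope must be 'run' or 'point', got {self.scope!r}")


@dataclass(frozen=True)
class MirroredSignal:
    """Signal with selected negative runs reflected about the baseline.

    ``mirrored_runs`` holds half-open ``(start, end)`` index ranges that were
    negated; outside them the samples equal the input.
    """

    samples: np.ndarray
    mirrored_runs: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class CandidateSet:
    """Sorted local-maximum positions with their amplitudes."""

    indices: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        indices = np.asarray(self.indices, dtype=np.int64)
        amplitudes = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "indices", indices)
        object.__setattr__(self, "amplitudes", amplitudes)
        if indices.size != amplitudes.size:
            raise ValueError("indices and amplitudes must have equal length")
        if indices.size and np.any(np.diff(indices) <= 0):
            raise ValueError("candidate indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    def subset(self, mask: np.ndarray) -> "CandidateSet":
        return CandidateSet(self.indices[mask], self.amplitudes[mask])


def local_maxima(signal: np.ndarray) -> CandidateSet:
    """Locate local maxima from the sign of the first-order difference.

    d[n] = x[n+1] - x[n] is mapped to its sign s[n] in {-1, 0, +1}; the
    difference of the sign sequence equals -2 exactly where a rise turns into
    a fall, and the maximum sits one sample to the right of that position.
    Zero signs (plateaus) inherit the nearest following nonzero sign, so a
    rise-plateau-fall contributes a single maximum at the first plateau
    sample; plateaus running into either end of the record contribute none.
    Endpoints are never reported.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate local maxima")
    s = np.sign(np.diff(x))
    # backward-fill zeros with the nearest following nonzero sign
    nz = np.where(s != 0, np.arange(s.size), s.size)
    nz = np.minimum.accumulate(nz[::-1])[::-1]
    filled = np.where(nz < s.size, s[np.minimum(nz, s.size - 1)], 0.0)
    dd = np.diff(filled)
    idx = np.flatnonzero(dd == -2) + 1
    return CandidateSet(idx, x[idx])


def _negative_run(x: np.ndarray, k: int) -> tuple[int, int]:
    """Half-open range of the contiguous run of negative samples containing k."""
    start = k
    while start > 0 and x[start - 1] < 0:
        start -= 1
    end = k + 1
    while end < x.size and x[end] < 0:
        end += 1
    return start, end


def mirror(signal: np.ndarray, fs: float, cfg: MirrorConfig | None = None) -> MirroredSignal:
    """Reflect dominant negative deflections about the zero baseline.

    Candidates are the negative local minima of the signal.  Each is tested
    independently against the original (pre-mirroring) samples; qualifying
    runs are negated on a copy.
    """
    cfg = cfg or MirrorConfig()
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if not cfg.enabled or x.size < 3:
        return MirroredSignal(x.copy())

    w = int(round(cfg.window_s * fs))
    minima = local_maxima(-x)
    out = x.copy()
    runs: list[tuple[int, int]] = []
    for k in minima.indices:
        k = int(k)
        if x[k] >= 0:
            continue
        lo = max(0, k - w)
        hi = min(x.size, k + w + 1)
        window = np.abs(x[lo:hi]).copy()
        if cfg.exclude_own_run:
            r0, r1 = _negative_run(x, k)
            window[max(lo, r0) - lo : min(hi, r1) - lo] = 0.0
        else:
            window[k - lo] = 0.0
        if abs(x[k]) >= cfg.amplitude_multiple * window.max(initial=0.0):
            if cfg.scope == "run":
                r0, r1 = _negative_run(x, k)
            else:
                r0, r1 = k, k + 1
            if (r0, r1) not in runs:
                runs.append((r0, r1))
                out[r0:r1] = -x[r0:r1]
    return MirroredSignal(out, tuple(runs))
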