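"""Independent reference implementations used as oracles in the tests.

Deliberately written as straight-line, loop-heavy code so they share no
logic with the library's vectorised implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def brute_local_maxima(x) -> list[int]:
    """Scan every interior sample for a strict-rise / plateau / strict-fall.

    A maximum is reported at the first sample of a plateau that is entered
    by a strict rise and left by a strict fall (a single-sample peak is a
    plateau of length one).  Plateaus touching either end yield nothing.
    """
    x = list(map(float, x))
    L = len(x)
    out = []
    for m in range(1, L - 1):
        if not x[m - 1] < x[m]:
            continue
        e = m
        while e + 1 < L and x[e + 1] == x[m]:
            e += 1
        if e + 1 < L and x[e + 1] < x[m]:
            out.append(m)
    return out


def steps_a_to_e(indices, widths, amplitudes, ti_t) -> list[int]:
    """Literal transcription of the five-step time-interval arbitration.

    ``indices`` are sorted candidate positions; ``widths`` and ``amplitudes``
    map position -> measure.  Returns the accepted positions.
    """
    cand = list(indices)
    peaks: list[int] = []
    if not cand:
        return peaks
    tref, cref = 0, 1
    while True:
        # Step A: if there is no Cref, Tref is a true R-peak and we stop.
        if cref >= len(cand):
            peaks.append(cand[tref])
            return peaks
        # Step B: compare the time period with ti_t.
        t_p = cand[cref] - cand[tref]
        if t_p >= ti_t:
            peaks.append(cand[tref])
            tref, cref = cref, cref + 1
            continue
        # Step C: narrower width wins; tie goes to Step D.
        wr, wf = widths[cand[tref]], widths[cand[cref]]
        if wr < wf:
            tref_wins = True
        elif wr > wf:
            tref_wins = False
        else:
            # Step D: larger amplitude wins; exact tie resolves to Cref.
            tref_wins = amplitudes[cand[tref]] > amplitudes[cand[cref]]
        # Step E: the false maximum is replaced by the next candidate.
        if not tref_wins:
            tref = cref
        cref += 1


def optimal_window_match(peaks, truth, tol) -> int:
    """Maximum-cardinality one-to-one matching within +/- tol samples."""
    peaks = list(peaks)
    truth = list(truth)
    if not peaks or not truth:
        return 0
    allowed = np.zeros((len(truth), len(peaks)), dtype=bool)
    for i, t in enumerate(truth):
        for j, p in enumerate(peaks):
            allowed[i, j] = abs(int(p) - int(t)) <= tol
    cost = 1.0 - allowed.astype(float)
    rows, cols = linear_sum_assignment(cost)
    return int(allowed[rows, cols].sum())
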