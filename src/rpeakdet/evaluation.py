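"""Beat-level evaluation: tolerance-window matching, SEN / +P / ACC, sweeps.

A detection is a true positive when it falls within a tolerance window
(default 50 ms) of a reference beat, each reference matching at most one
detection.  From the TP / FN / FP counts:

    SEN = 100 * TP / (TP + FN)        sensitivity
    +P  = 100 * TP / (TP + FP)        positive predictivity
    ACC = 100 * TP / (TP + FN + FP)   accuracy

Multi-record totals pool the raw counts before taking percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BeatAnnotations, EcgRecord, RPeakSet
from .mirror import MirrorConfig
from .thresholding import ThresholdParams, detect

__all__ = ["EvalReport", "SweepResult", "match", "metrics", "evaluate_record", "pooled_report", "sweep"]

DEFAULT_TOLERANCE_S = 0.05


@dataclass(frozen=True)
class EvalReport:
    record_id: str
    total_beats: int
    tp: int
    fn: int
    fp: int
    sen: float
    pos_pred: float
    acc: float

    def as_row(self) -> dict:
        """One CSV row: Record, Total beats, TP, FN, FP, SEN, +P, ACC."""
        return {
            "Record": self.record_id,
            "Total beats": self.total_beats,
            "TP": self.tp,
            "FN": self.fn,
            "FP": self.fp,
            "SEN": round(self.sen, 2),
            "+P": round(self.pos_pred, 2),
            "ACC": round(self.acc, 2),
        }


def match(
    peaks: RPeakSet | Sequence[int],
    truth: BeatAnnotations | Sequence[int],
    fs: float,
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> tuple[int, int, int]:
    """One-to-one matching of detections to reference beats.

    Greedy nearest-neighbour in increasing time: each reference beat takes
    the closest unmatched detection within ±round(tol_s*fs) samples, ties to
    the earlier detection.  Returns (TP, FN, FP).
    """
    if tol_s <= 0:
        raise ValueError("tolerance must be positive")
    p = np.asarray(getattr(peaks, "indices", peaks), dtype=np.int64)
    t = np.asarray(getattr(truth, "indices", truth), dtype=np.int64)
    tol = int(round(tol_s * fs))
    tp = 0
    j = 0
    n = p.size
    for beat in t:
        while j < n and p[j] < beat - tol:
            j += 1
        best = -1
        best_d = tol + 1
        k = j
        while k < n and p[k] <= beat + tol:
            d = abs(int(p[k]) - int(beat))
            if d < best_d:  # strict: ties keep the earlier detection
                best, best_d = k, d
            k += 1
        if best >= 0:
            tp += 1
            j = best + 1
    return tp, t.size - tp, n - tp


def metrics(tp: int, fn: int, fp: int, record_id: str = "") -> EvalReport:
    """SEN / +P / ACC percentages from beat counts."""
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fn
    if total == 0:
        raise ValueError("undefined metrics: no reference beats (TP + FN = 0)")
    sen = 100.0 * tp / (tp + fn)
    pos_pred = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    acc = 100.0 * tp / (tp + fn + fp)
    return EvalReport(record_id, total, tp, fn, fp, sen, pos_pred, acc)


def evaluate_record(
    rec: EcgRecord,
    truth: BeatAnnotations,
    params: ThresholdParams | None = None,
    mirror_cfg: MirrorConfig | None = None,
    tol_s: float = DEFAULT_TOLERANCE_S,
    **detect_kwargs,
) -> EvalReport:
    """Run the detector on one record and score it against its annotations."""
    peaks = detect(rec, params, mirror_cfg, **detect_kwargs)
    tp, fn, fp = match(peaks, truth, rec.fs, tol_s)
    return metrics(tp, fn, fp, rec.record_id)


def pooled_report(reports: Iterable[EvalReport], record_id: str = "Total") -> EvalReport:
    """Aggregate per-record reports by pooling the raw counts.

    Percentages are recomputed from the pooled TP/FN/FP, not averaged over
    records, so large records weigh proportionally more.
    """
    tp = fn = fp = 0
    for r in reports:
        tp, fn, fp = tp + r.tp, fn + r.fn, fp + r.fp
    return metrics(tp, fn, fp, record_id)


@dataclass(frozen=True)
class SweepResult:
    """Pooled evaluation for every (K_amp, K_time) grid cell."""

    grid: dict[tuple[float, float], EvalReport]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (k_amp, k_time), rep in sorted(self.grid.items()):
            rows.append({"K_amp": k_amp, "K_time": k_time, "TP": rep.tp,
                         "FN": rep.fn, "FP": rep.fp, "SEN": round(rep.sen, 2),
                         "+P": round(rep.pos_pred, 2), "ACC": round(rep.acc, 2)})
        return pd.DataFrame(rows)


def sweep(
    records: Sequence[tuple[EcgRecord, BeatAnnotations]],
    k_amp_grid: Sequence[float],
    k_time_grid: Sequence[float],
    params: ThresholdParams | None = None,
    mirror_cfg: MirrorConfig | None = None,
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> SweepResult:
    """Evaluate the detector over a grid of threshold coefficients.

    Each cell reruns the full detector with that (K_amp, K_time) pair on
    every record and pools the counts before computing percentages.
    """
    if not len(k_amp_grid) or not len(k_time_grid):
        raise ValueError("coefficient grids must be non-empty")
    base = params or ThresholdParams()
    grid: dict[tuple[float, float], EvalReport] = {}
    for k_amp in k_amp_grid:
        for k_time in k_time_grid:
            cell_params = ThresholdParams(k_amp, k_time, base.segment_s,
                                          base.width_cap_s)
            reports = [
                evaluate_record(rec, truth, cell_params, mirror_cfg, tol_s)
                for rec, truth in records
            ]
            grid[(k_amp, k_time)] = pooled_report(reports)
    return SweepResult(grid)
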