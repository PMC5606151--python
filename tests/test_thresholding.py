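"""Adaptive thresholds, width measurement, Steps A-E arbitration, detect()."""

import numpy as np
import pytest

from rpeakdet.io import EcgRecord
from rpeakdet.mirror import CandidateSet, MirrorConfig, local_maxima
from rpeakdet.thresholding import (
    ThresholdParams,
    amplitude_filter,
    detect,
    peak_width,
    recognize,
    run_detector,
    segment_thresholds,
)
from rpeakdet.evaluation import evaluate_record, match
from reference_impl import steps_a_to_e

FS = 360.0


def cand(indices, amplitudes):
    return CandidateSet(np.asarray(indices), np.asarray(amplitudes))


class TestSegmentThresholds:
    def test_amplitude_threshold_arithmetic(self):
        # K_amp = 0.25 of a 2.0 mV segment maximum -> a_t = 0.5 mV
        sig = np.zeros(3600)
        sig[[100, 388, 676]] = [2.0, 1.8, 1.9]
        c = local_maxima(sig)
        th = segment_thresholds(c, sig, (0, 3600), ThresholdParams(), FS)
        assert th.max_seg_amp == 2.0
        assert th.a_t == pytest.approx(0.5)

    def test_time_threshold_from_survivor_spacing(self):
        # survivors every 0.8 s at 360 Hz -> AVE = 288 samples, ti_t = 129.6
        idx = np.arange(12) * 288 + 10
        sig = np.zeros(3600)
        sig[idx] = 1.0
        c = local_maxima(sig)
        th = segment_thresholds(c, sig, (0, 3600), ThresholdParams(), FS)
        assert th.ave_max_dis == pytest.approx(288.0)
        assert th.ti_t == pytest.approx(0.45 * 288)

    def test_empty_segment_bootstraps_from_nominal_rr(self):
        sig = np.zeros(3600)
        c = cand([], [])
        th = segment_thresholds(c, sig, (0, 3600), ThresholdParams(), FS)
        assert th.bootstrapped
        assert th.ti_t == pytest.approx(0.45 * 0.82 * FS)

    def test_empty_segment_inherits_previous(self):
        sig = np.zeros(3600)
        th = segment_thresholds(cand([], []), sig, (0, 3600), ThresholdParams(),
                                FS, prev_ti_t=117.0)
        assert th.ti_t == 117.0


class TestAmplitudeFilter:
    def test_strictly_above_threshold_survives(self):
        c = cand([10, 20, 30], [0.1, 0.6, 0.4])
        out = amplitude_filter(c, 0.5)
        np.testing.assert_array_equal(out.indices, [20])

    def test_zero_threshold_keeps_positive_amplitudes(self):
        c = cand([10, 20, 30], [0.5, 0.0, 1.0])
        out = amplitude_filter(c, 0.0)
        np.testing.assert_array_equal(out.indices, [10, 30])

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(50):
            n = rng.integers(1, 80)
            idx = np.sort(rng.choice(10_000, size=n, replace=False))
            amp = rng.normal(size=n)
            a_t = float(abs(rng.normal()))
            out = amplitude_filter(cand(idx, amp), a_t)
            keep = [i for i, a in zip(idx, amp) if a > a_t]
            np.testing.assert_array_equal(out.indices, keep)


class TestPeakWidth:
    def test_triangle_pulse(self):
        sig = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        assert peak_width(sig, 2, FS) == 4

    def test_rectangular_pulse(self):
        w = 11
        sig = np.zeros(300)
        sig[100:100 + w] = 1.0
        got = peak_width(sig, 105, FS)
        assert abs(got - (w + 1)) <= 1

    def test_plateau_wider_than_cap_hits_cap(self):
        sig = np.ones(1000)
        sig[500] = 2.0
        cap = int(round(0.278 * FS))
        assert peak_width(sig, 500, FS) == 2 * cap

    def test_requires_positive_peak(self):
        with pytest.raises(ValueError):
            peak_width(np.array([0.0, -1.0, 0.0]), 1, FS)


class TestRecognize:
    def sig_with_peaks(self, layout, n=2000):
        """Triangular peaks at given (index, amplitude, half_width)."""
        sig = np.zeros(n)
        for idx, amp, half in layout:
            ramp = amp * (1 - np.abs(np.arange(-half, half + 1)) / (half + 1))
            sig[idx - half:idx + half + 1] += ramp
        return sig

    def test_widely_spaced_candidates_all_accepted(self):
        sig = self.sig_with_peaks([(500, 1.0, 5), (900, 1.0, 5)])
        c = amplitude_filter(local_maxima(sig), 0.5)
        assert recognize(c, 130.0, sig, FS) == [500, 900]

    def test_narrower_peak_wins_close_pair(self):
        # widths ~10 vs ~40 samples, 60 samples apart, ti_t 130
        sig = self.sig_with_peaks([(1000, 1.0, 5), (1060, 1.0, 20)])
        c = amplitude_filter(local_maxima(sig), 0.5)
        assert recognize(c, 130.0, sig, FS) == [1000]

    def test_loser_replaced_by_next_candidate(self):
        # wide first peak loses to narrow second; third is far away
        sig = self.sig_with_peaks([(1000, 1.0, 20), (1060, 1.0, 5),
                                   (1400, 1.0, 6)])
        c = amplitude_filter(local_maxima(sig), 0.5)
        assert recognize(c, 130.0, sig, FS) == [1060, 1400]

    def test_width_tie_resolved_by_amplitude(self):
        sig = self.sig_with_peaks([(1000, 1.0, 5), (1060, 0.8, 5)])
        c = amplitude_filter(local_maxima(sig), 0.5)
        assert recognize(c, 130.0, sig, FS) == [1000]
        sig2 = self.sig_with_peaks([(1000, 0.8, 5), (1060, 1.0, 5)])
        c2 = amplitude_filter(local_maxima(sig2), 0.5)
        assert recognize(c2, 130.0, sig2, FS) == [1060]

    def test_previous_segment_peak_suppresses_leading_duplicate(self):
        sig = self.sig_with_peaks([(100, 1.0, 5), (500, 1.0, 5)])
        c = amplitude_filter(local_maxima(sig), 0.5)
        assert recognize(c, 130.0, sig, FS, prev_index=30) == [500]

    def test_empty_input(self):
        assert recognize(cand([], []), 130.0, np.zeros(100), FS) == []

    def test_matches_literal_transcription_on_random_sets(self, rng):
        for _ in range(100):
            n_peaks = int(rng.integers(2, 15))
            idx = np.sort(rng.choice(np.arange(50, 1950, 10), size=n_peaks,
                                     replace=False))
            layout = [(int(i), float(rng.uniform(0.5, 2.0)),
                     int(rng.integers(3, 30))) for i in idx]
            sig = self.sig_with_peaks(layout)
            c = amplitude_filter(local_maxima(sig), 0.3)
            ti_t = float(rng.uniform(20, 400))
            widths = {int(i): peak_width(sig, int(i), FS) for i in c.indices}
            amps = {int(i): float(sig[i]) for i in c.indices}
            expected = steps_a_to_e(list(map(int, c.indices)), widths, amps, ti_t)
            assert recognize(c, ti_t, sig, FS) == expected


class TestDetect:
    def test_clean_fixture_all_beats_within_tolerance(self, clean_fixture):
        rec, ann = clean_fixture
        peaks = detect(rec)
        tp, fn, fp = match(peaks, ann, rec.fs)
        assert fn == 0 and fp == 0

    def test_pvc_fixture_mirroring_ablation(self, pvc_fixture):
        rec, ann = pvc_fixture
        sen_on = evaluate_record(rec, ann).sen
        sen_off = evaluate_record(rec, ann,
                                  mirror_cfg=MirrorConfig(enabled=False)).sen
        assert sen_on >= 100 * 58 / 60
        assert sen_off < sen_on

    def test_flat_signal_yields_no_peaks(self):
        rec = EcgRecord("flat", np.zeros(3600), FS)
        assert len(detect(rec)) == 0

    def test_output_gaps_respect_segment_ti_t(self, mixed_fixture):
        rec, _ = mixed_fixture
        res = run_detector(rec)
        idx = res.peaks.indices
        seg_len = int(round(10.0 * rec.fs))
        for a, b in zip(idx[:-1], idx[1:]):
            th = res.segments[min(b // seg_len, len(res.segments) - 1)]
            assert b - a >= th.ti_t

    def test_raising_k_amp_never_increases_detections(self, mixed_fixture):
        rec, _ = mixed_fixture
        counts = [
            len(detect(rec, ThresholdParams(k_amp, 0.45)))
            for k_amp in (0.10, 0.20, 0.25, 0.30, 0.40, 0.50)
        ]
        assert counts == sorted(counts, reverse=True)
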