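# Methods

## Detection model

`rpeakdet` treats R-peak detection as local-maximum selection on an
enhanced, rectified signal.  The assumptions are: (i) after enhancement the
baseline is zero, so "negative deflection" and "below baseline" coincide;
(ii) R-peaks are the narrowest large deflections in the record — P and T
waves are wider along the baseline, noise spikes are smaller than
K_amp times the local maximum; (iii) two true beats are never closer than
K_time times the average local-maximum spacing.  Violations of (ii) and
(iii) are exactly the failure modes the synthetic fixtures probe.

### Wavelet enhancement

Decimated 8-level DWT (`bior6.8`, symmetric boundary extension),
reconstruction trimmed to the input length.  The level count is fixed at 8
for every sampling rate, which puts the approximation band below ~0.7 Hz at
360 Hz and ~0.5 Hz at 250 Hz — the baseline-drift range.  Band selection
zeroes cA8 always and cD1 when its lower edge f_s/4 ≥ 90 Hz, a single rule
that reduces to "drop cD1 at 360 Hz, keep it at 250 Hz"; an explicit
keep-set overrides it.  A symmetric (linear-phase) wavelet is used so that
reconstruction does not displace peak positions.

Soft thresholding uses λ_j = σ·√(2 ln N_j) per retained detail level, with
a *single* noise scale σ = median(|cD1|)/0.6745 estimated from the finest
level before any band is zeroed.  Estimating σ per level from that level's
own coefficients was tried first and rejected: mid levels carry the QRS
energy, their MAD is inflated by signal, and the resulting thresholds ate
40–50 % of the R amplitude (unevenly — widened PVC complexes lost most),
which defeats an amplitude threshold defined as a fraction of the local
maximum.  The finest level is almost pure noise for a band-limited
physiological signal, making its MAD the standard robust noise estimate.
`shrinkage="none"` disables the step.

### Mirroring

Candidates for reflection are the negative local minima.  A candidate at k
is reflected when |x[k]| ≥ 1.5·|x[i]| for every comparison sample i within
±0.278 s.  The comparison set excludes the contiguous negative run
containing k: the samples on the flanks of a spike are nearly as deep as
its tip, so a strictly pointwise rule can never fire on a densely sampled
smooth waveform — the exclusion restores the intended meaning ("the spike
dominates its surroundings") while keeping the veto by any *other* large
deflection, positive or negative, inside the window.
`exclude_own_run=False` restores the literal pointwise rule.  The whole
negative run is reflected (scope `"run"`), so the mirrored complex keeps
its shape; `"point"` flips only the extremum.  Each candidate is judged
against the original samples, independently of other reflections.

### Local maxima

Sign-of-difference with a plateau convention: zero signs inherit the
nearest *following* nonzero sign, so a rise–plateau–fall yields one maximum
at the first plateau sample and plateaus touching the record ends yield
none.  Endpoints are never candidates.  The brute-force scan used as the
oracle in the tests encodes the same convention independently.

### Adaptive thresholds

Contiguous, non-overlapping 10 s segments.  a_t = K_amp·(segment maximum of
the mirrored signal); MAX_seg_amp is taken from the signal rather than from
the candidate amplitudes (numerically near-identical, and well-defined even
when no candidate lies in the segment).  AVE_max_dis is the mean spacing of
the candidates that *survive* a_t — raw maxima include noise ripples whose
spacing would collapse ti_t far below any RR interval; with survivors,
ti_t ≈ K_time·RR.  A segment with fewer than two survivors inherits the
previous ti_t, or bootstraps it from a nominal 0.82 s RR (the midpoint of
the common 0.54–1.19 s range) when it is the first.

Arbitration of a candidate pair closer than ti_t: smaller baseline width
wins; width tie → larger amplitude wins; exact amplitude tie → the later
candidate wins.  The winner keeps the reference role and faces the next
candidate.  The last accepted peak of a segment suppresses leading
candidates of the next segment closer than the new segment's ti_t, so
accepted peaks are always separated by at least the governing ti_t.

Peak width is measured as the distance between the nearest "baseline
returns" on either side: the first sample at or below
max(0, 0.05·peak amplitude), searched at most 0.278 s per side (a side
without a return contributes the cap).  The 5 % level rather than a strict
zero crossing matters for mirrored complexes, whose neighbourhood is
strictly positive after reflection; with a strict zero the width of every
mirrored peak saturated at the cap and the comparison degenerated.  The
0.278 s cap reuses the mirroring window — the one locality constant in the
method.

### Defaults

| parameter | default | units | role |
|---|---|---|---|
| K_amp | 0.25 | — | a_t as a fraction of the segment maximum |
| K_time | 0.45 | — | ti_t as a fraction of the survivor spacing |
| segment_s | 10 | s | threshold update interval |
| amplitude_multiple | 1.5 | — | mirroring dominance factor |
| window_s / width_cap_s | 0.278 | s | mirroring window and width cap |
| tolerance | 0.05 | s | beat-matching window |
| wavelet / levels | bior6.8 / 8 | — | enhancement basis |

Recommended operating ranges are K_amp ∈ [0.2, 0.3] and
K_time ∈ [0.42, 0.48]; larger K_amp trades sensitivity for positive
predictivity monotonically.

## Evaluation

Greedy nearest-neighbour matching in increasing time, one detection per
reference beat, ties to the earlier detection; for physiological RR
intervals the ±50 ms windows are disjoint and greedy matching is optimal
(verified against an assignment-problem matcher in the tests).  Multi-record
totals pool TP/FN/FP before taking percentages, so long records weigh more
than short ones — record-averaged percentages would differ.

## Synthetic data

Each beat is a sum of five Gaussians (P, Q, R, S, T) with amplitudes
0.15/−0.10/1.00/−0.15/0.23 mV, offsets −0.20/−0.035/0/0.035/0.25 s and
widths 25/10/12/10/60 ms; the R/T amplitude ratio is ≈ 4.3 and the QRS
spans ~70 ms, within common clinical ranges.  Beats are placed at
RR-jittered onsets (mean 0.8 s) with a 0.3 s physiological floor.  PVC-like
beats negate and double-widen R and enlarge T by 1.5×; small beats scale R
by 0.35.  Optional sinusoidal drift, powerline interference and white noise
are added on top.  All randomness flows through one seeded generator.

The presets fix the study conditions: `clean` (150 periodic beats, 120 s,
light noise), `pvc` (48 s, 30 % PVC), `drift` (0.5 mV at 0.25 Hz),
`large_t` (T raised to 0.5 mV), `mixed_amplitude` (half the beats at 0.35×
R), `noisy` (0.1 mV noise + 50/60 Hz interference).  These sizes — 1–2
minutes at 360 Hz per condition — are large enough for ~10 threshold
segments per record while keeping the whole suite interactive.

What the generator does *not* emulate: morphology drift within a record,
electrode pop/motion artifacts, rhythm pathology beyond isolated PVC
timing, multiform ectopy, and real measurement noise spectra.  Perfect
scores on `clean`/`drift`/`noisy` therefore demonstrate the mechanics of
the pipeline, not clinical-grade performance; benchmarking on the MIT-BIH
arrhythmia and QT databases (supported via the WFDB reader, first channel)
is the real test and requires downloading those databases.

## Known limitations

- **Small R among large R** (`mixed_amplitude`): a_t follows the segment
  maximum, so 0.35× beats sit near the threshold and some are lost
  (sensitivity ~90 % at K_amp = 0.25, recovering as K_amp decreases).  This
  is inherent to a segment-global amplitude threshold.
- **Uniformly large T waves** (`large_t`): when *every* T clears a_t the
  survivor spacing halves, ti_t collapses below the R→T gap and the T
  waves are accepted (+P ≈ 50 %).  The interval arbitration only rejects
  *occasional* intruders; a morphology feature would be needed here.
- No search-back: a beat suppressed by an overestimated ti_t is never
  recovered.
- Annotation totals on real databases depend on which symbols count as
  beats; this package counts the standard beat codes only, so totals may
  differ by a handful of beats from other implementations.
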