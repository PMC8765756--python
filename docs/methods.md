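# Methods

This note documents the models, conventions, defaults, and design choices
behind the pipeline, and what the synthetic-data tests do and do not
establish about real recordings.

## Session model and preprocessing

A session holds region-labelled units (LC or ACC) with per-trial spike
times in ms relative to trial start, per-trial event times (fixation
onset, stable-fixation onset, optional beep, trial end), and a uniformly
sampled pupil trace in arbitrary units (pupil diameter is never
calibrated).  Gaze quality control is stored as a per-trial pass/fail
summary; cleaning raw eye traces is upstream of this package.  The on-disk
format is a directory of one JSON manifest and three CSV tables, written
deterministically and parsed back bit-exactly (`float_precision=
"round_trip"`).

All spiking analyses run inside the stable-fixation epoch: a 1.1 s window
starting 1 s after stable fixation is attained.  Trials whose gaze flag
fails or that end before the window does are excluded.  Counting windows
are half-open `[start, start + bin)` and anchored at the epoch start — one
window per trial per bin size, not an average over tiled windows (the
tiling alternative would mix non-stationarity across the epoch into the
counts).

## Single-unit statistics and conditioning

Mean, sample variance (n−1), and Fano factor (variance/mean; undefined and
flagged, not 0 or ∞, when the mean is 0) are computed per unit, bin size
(five linear bins 200 ms–1 s, or ten log bins 100 ms–1 s), and condition.
Conditions come from the partner region's spike count in the reference
window: groups 0/1/2/3/4+ plus the derived zero vs nonzero split.  The
groups are interpreted as spike *counts* in the 1.1 s window: the zero
group is literally "no spikes", which forces the count reading over a
rate reading.  Conditions with fewer than `min_trials = 5` trials are
flagged missing rather than silently dropped.  The conditioning machinery
is region-agnostic, so the symmetric analysis (ACC counts conditioning LC
statistics) is the same function with arguments swapped.

## Pairwise correlations

Per pair, condition, and bin size: z-score both count vectors (sample SD;
constant vectors flagged undefined), remove trials where either |z| > 3 in
one pass (z-scores from the full condition, strictly-greater removes,
boundary kept), then Pearson-correlate the survivors; below `min_trials=5`
the record is flagged missing.  Z-scoring and outlier removal happen
within the trial set being correlated; z-scoring across all trials before
conditioning is the documented alternative but is not the default, since
the removal rule is defined relative to the response distribution actually
entering the correlation.  The condition-independent r_sc (computed on all
trials per bin size) assigns each pair to a tercile by rank, stable order
breaking ties, sizes differing by at most one with extras to lower
terciles.  The shuffle control permutes each unit's count vector
independently across trials, destroying the trial pairing while preserving
the marginals; its correlation null has mean 0 and SD ≈ 1/√(n−1).

## Pupil phase

Hippus cycles are delimited by successive local minima of the
moving-average-smoothed trace (default 50 ms smoothing; minima must have
prominence ≥ 0.2 pupil units, which suppresses cycle detection on
unmodulated noise), with the in-cycle maximum and the extrema of the
smoothed derivative providing the four landmarks: maximum dilation rate
0°, maximum size 90°, maximum constriction rate 180°, minimum size 270°.
Phase is linear in time between landmarks, undefined outside complete
cycles, and invariant under adding a constant to the trace.

Phase-triggered maps use 36 × 10° phase bins, offsets −1000…+1000 ms in
100 ms steps, 500 ms-wide windows, and a minimum of 10 occurrences per
cell (all configurable; only the 500 ms window width is inherited from the
measured analyses this emulates).  Rate maps are z-scored per unit across
defined cells; correlation maps hold the pair's Pearson r across
occurrences.  The precession fit takes the extremum phase per offset
(peaks for rate, minima for r_sc), unwraps by ±360° to minimize successive
jumps, and fits phase = slope·t + b by least squares; fits with slope-vs-0
p ≥ 0.05 or a constant extremum sequence are flagged unreliable.  The
delay is reported as the time by which the signal's modulation leads the
0° landmark: minus the line's 0°-crossing, folded into one precession
period.  With period T the analytic slope is −360/T; note that a slope of
−0.33 deg/ms would imply T ≈ 1100 ms, so slope and period cannot both
match arbitrary values — the fit reports what the data contain.

## Evoked analyses

PSTHs are trial-averaged rates with SEM; the Fano time course uses 200 ms
sliding windows.  The evoked-LC criterion is a parameterized contract:
responsive ⇔ count ≥ 2 in the 300 ms burst window and count ≤ 0 in the
following 500 ms pause window (all four numbers configurable).  Its
false-alarm rate on rate-R Poisson spiking is the closed form
P(Pois(0.3·R) ≥ 2)·P(Pois(0.5·R) = 0), which anchors the calibration.
Fake-beep classification applies the same detector at a virtual time drawn
uniformly 1–1.5 s after stable fixation (the real beep schedule), seeded.
Pre/post correlation differences use the 1 s windows before/after the
event with counting bins anchored at each window's start; pupil responses
use a 1 s pre-event baseline and a 2 s post-event search window, with
median splits per session.  Event-aligned r_sc time courses use 500 ms
windows stepped by 100 ms, rank-sum tests per window against the pre-event
baseline windows, and a per-pair linear slope over a configurable early
epoch compared between groups.

## Statistics

Sign-rank (Wilcoxon), rank-sum (Mann–Whitney), two-sample KS, and one-way
ANOVA wrap scipy.stats with exact small-sample paths (n ≤ 25, tie-free)
and tie-corrected asymptotics otherwise; the multi-factor design is a
two-factor fixed-effects ANOVA with interaction via statsmodels.
Bootstrap CIs are percentile intervals of the median over 1000 seeded
resamples.  All randomness flows through explicitly passed
`numpy.random.Generator` objects.

## Synthetic generator: what it emulates, and its defaults

The generator reproduces the statistical structure the analyses assume,
with every target analytic:

* **ACC pairs — common-input Poisson blocks.**  Counts N₁ = B₁ + C,
  N₂ = B₂ + C with Bᵢ ~ Pois(λ_b), C ~ Pois(λ_c) per block give block-level
  r = λ_c/(λ_b+λ_c) exactly.  Each unit scatters the *same* shared count at
  *independent* uniform times, so a sub-window of length b thins both
  counts independently and r(b) = (b/W)·r_W grows linearly toward the
  block value — the qualitative bin-size dependence of cortical r_sc.
  (Scattering shared spikes at identical times would instead make r flat
  in bin size and introduce millisecond synchrony the analyses do not
  assume.)  Marginals stay Poisson, so the per-condition Fano target is 1.
* **Gates.**  `lc_gate` switches (λ_b, λ_c) on the stable-fixation block by
  the *realized* LC count (defaults 1.2 → 0.4 shared of a fixed total 4,
  implying a conditioned difference of −0.2 with no rate signature);
  `evoked_gate` switches the 1 s pre/post-beep blocks (defaults 0.5 → 1.5
  shared of total 4 on responsive trials, +0.25).  On no-beep trials,
  event-gated pairs are tiled with 1 s baseline blocks so that pre/post
  windows around any virtual (fake-beep) time are exchangeable.  Remaining
  stretches are rate-matched but uncorrelated filler.
* **LC unit.**  Inhomogeneous Poisson, base 2 sp/s, rate modulated
  1 + m·cos(2π(t+d)/T + φ₀) with the same per-trial phase φ₀ as the pupil
  sinusoid, so the unit leads the pupil's maximum-dilation-rate landmark by
  d (default 270 ms; hippus period T default 600 ms).  Trials are
  zero-inflated (probability 0.3 of a silent trial) so that over a third of
  passive-fixation trials carry no LC spike while the median nonzero rate
  stays near 2 sp/s — matching the firing regime these analyses must cope
  with.  Responsive beep trials (half of beeps) add a 40 Hz, 200 ms burst
  then a hard 600 ms pause; the evoked burst also fires on silent trials
  (startle overrides the low-arousal state).
* **Pupil.**  A·sin(2πt/T + φ₀) plus 50 ms-smoothed Gaussian noise
  (sd 0.05), plus on beep trials a dilation kernel (500 ms linear ramp,
  1 s exponential decay) whose amplitude scales with the realized burst
  count, giving the positive burst-size/dilation correlation.
* **Trials.**  Fixed 4 s (the recordings' 1–5 s variable length adds
  nothing to the statistics under test and a fixed length guarantees every
  trial admits the stable-fixation window and both beep windows); beeps on
  25% of trials, 1–1.5 s after stable fixation; fixation at 0, stable
  fixation at 200 ms.  Each pair uses its own two units; pairs sharing
  units (as in real multi-electrode sessions) would correlate pair-level
  estimates without changing any per-pair expectation.

What passing these tests shows: the pipeline's estimators recover known
correlation structure, conditioned differences, phase relationships, and
evoked contrasts without bias at realistic firing rates and trial counts.
What they do not show: robustness to features the generator omits —
non-Poisson spiking (bursting, refractoriness), drift and slow
nonstationarity, electrode artifacts, blink gaps in the pupil trace,
heterogeneous pair overlap, or gaze-correlated sampling.  Conclusions
about real data still require the controls the pipeline itself provides
(shuffles, fake beeps, terciles).

## Problem sizes and numerical choices

Calibration experiments use: 100 pairs × 5000 trials (correlation
identity); 100 pairs × 400 trials plus one pair × 5000 trials
(conditioned difference and rate independence); 1000 shuffles of a
1000-trial pair and 50 pairs × 400 trials (shuffle null); 10 000 trials
(Poisson Fano, detector false alarms) and 5000 (gain quenching); 20
seeded simulations of 300 × 3 s trials (phase slope/delay); 60 pairs × 400
trials with beeps on half (pre/post contrasts); 300 replicates per test
(null uniformity — sign-rank at n=50 and KS at co-prime sizes 100/103,
where the discrete p-value supports are fine enough for a
uniformity check against the continuous uniform).  These sizes put each
analytic target well inside the estimators' resolving power while keeping
a full run around half a minute.

Degenerate inputs are contracts, not crashes: constant vectors flag
undefined z-scores/correlations, zero-mean windows flag undefined Fano,
below-minimum conditions flag missing records, flat pupil traces yield no
cycles, and constant phase-extremum sequences yield an unreliable fit.

## Known limitations

* The evoked-response criterion is declared, not estimated from data; the
  measured analyses it emulates never state theirs.
* The hippus period is a free parameter: the quoted ~600 ms period and the
  ~−0.33 deg/ms measured slope are mutually inconsistent with the −360/T
  identity, and the pipeline makes no attempt to reconcile them.
* Phase maps assume blink-free pupil traces.
* The two-factor ANOVA treats trial groups as fixed effects; no
  multiple-comparison correction is applied anywhere, matching the
  analyses being reproduced.
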