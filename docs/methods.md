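# Methods

## The OP_IBS index

A recording's PP-interval series is cut into consecutive 5-minute epochs
(300 s of cumulative interval time). Each epoch is mean coarse-grained with
scale factor `s` (non-overlapping block means, remainder discarded), embedded
into sliding words of length `m` with time delay `tau`, and each word is
reduced to its ordinal pattern: the permutation `(t1..tm)` giving, for each
ascending value rank, the original position of the element holding it. Equal
values are ordered by time of appearance (a stable ascending sort), so the
tied triple (1.01, 1.01, 0.90) maps to (3, 1, 2). Patterns are indexed by the
lexicographic order of their tuples — the only convention consistent with the
anchor (3, 1, 2) = pattern 5 for m = 3 — computed via the Lehmer code.

Within an epoch the `T = m!` classes are ranked by occurrence frequency,
ties (including the block of unobserved, zero-probability classes) broken by
ascending catalogue index. Two epochs are compared by the entropy-weighted
mean absolute rank difference (weights: summed pointwise Shannon entropy
terms of the two probability vectors, normalised to unit sum). The
per-recording index is the mean over adjacent epoch pairs. Epochs with fewer
than `s * ((m-1)*tau + 1)` beats cannot be coarse-grained and embedded and
are skipped with a warning; pairing runs over the surviving ordered list.

Properties relied on by the tests: the distance is symmetric, zero on
identical profiles, bounded by `(T-1)/T`, and invariant to the logarithm base
(the normalisation cancels it; natural log is used internally). When both
profiles are degenerate single-pattern profiles the normaliser is zero and
uniform weights `1/T` are substituted, which reduces the distance to the mean
absolute rank gap over `T` — in particular two identical degenerate profiles
still give 0.

Defaults `s = 7, m = 5, tau = 1`. At a typical 1 s pulse period a 5-min epoch
yields ~42 coarse samples and ~38 words against 120 classes: profiles are
deliberately sparse, which is what makes them sensitive to whether adjacent
epochs share the same few dominant temporal motifs. `parameter_sweep`
reproduces the selection surface (|Pearson R| against AHI over s = 4..10,
m = 2..6); |R| rather than signed R is maximised.

## Classic IBS

The comparator index binarizes interval increments (1 where the next interval
is strictly longer; ties, being "not greater", give 0), forms sliding D-bit
words (default D = 5, 32 classes, most significant bit earliest), and applies
the identical rank-and-distance machinery. No coarse-graining is applied on
this path.

## Time- and frequency-domain indices

Time domain per epoch: Mean; SDNN with the population normaliser 1/N; RMSSD
over the N−1 successive differences; PNN50 as the percentage of the N−1
successive differences exceeding 50 ms (the standard pair-count denominator);
CV = SDNN/Mean. PNN50 is intentionally not scale-equivariant (absolute 50 ms
threshold); the other indices scale linearly and CV is scale-free.

Frequency domain per epoch: the tachogram (interval value at the beat's
cumulative time) is resampled evenly at 4 Hz by cubic spline, mean-removed,
and fit with a Burg autoregressive model of order 16 (statsmodels'
implementation); the AR spectrum is integrated over the LF (0.04–0.15 Hz) and
HF (0.15–0.4 Hz) bands by trapezoid on a 16 385-point frequency grid. The
dense grid matters: AR spectra of near-periodic tachograms have very narrow
peaks whose band mass a coarse grid undersamples. LF/HF is reported as NaN
(never 0 or infinity) when HF is numerically zero. Epochs shorter than 60 s
are rejected. Per-recording values of every index are means over epochs,
mirroring the per-recording averaging of the similarity indices; NaN epochs
are excluded from the LF/HF mean.

## Preprocessing

Peak detection follows the two-moving-average scheme for PPG systolic peaks:
band-pass 0.5–8 Hz (order-2 zero-phase Butterworth), clip at zero, square;
blocks where the 111 ms moving average exceeds the 667 ms moving average plus
`beta = 0.02` times the mean squared signal, and that last at least one
peak-width, each contribute their band-passed maximum as a beat. All three
parameters are exposed.

The local median filter replaces an interval deviating from the median of its
11-beat neighbourhood by more than 20% of that median (a fractional rule,
robust to the absolute pulse-period scale). The rule is applied repeatedly to
a fixpoint, making the correction idempotent: removing a gross artifact can
lower a neighbourhood median enough to expose a second, milder one that a
single pass would leave in place. A window wider than the series degrades to
the global median. Replacement (rather than beat deletion) was chosen so that
epoch boundaries and beat counts stay stable.

Segmentation packs intervals into consecutive 300 s windows by cumulative
interval time (wall-clock timestamps are not required). A trailing window
whose data end before the full duration has elapsed is dropped, as is any
completed window with fewer than 60 beats — even at pathologically slow pulse
rates a genuine 5-min epoch comfortably exceeds 60 beats, so this only
removes windows that could not support coarse-graining at s = 7 with m = 5
embedding anyway.

## Synthetic recordings

The generator emulates exactly the features of PP-interval data the indices
respond to, beat by beat: pulse period = baseline (1.0 s; per-subject
U(0.85, 1.1) s in cohorts) + LF sinusoid (0.02 s at 0.1 Hz, Mayer-wave band)
+ respiratory sinus arrhythmia (0.03 s at 0.25 Hz) + white noise
(SD 0.02 s) + the apnea signature: at Poisson-distributed start times with
the configured hourly rate, a zero-mean sine over 45 s — one bradycardia
half-cycle then a symmetric tachycardia half-cycle of 0.15 s amplitude.
Intervals are floored at a quarter of the baseline so extreme noise draws
cannot produce non-positive beats. The event rate is returned as the AHI
label; cohorts draw rates from U(0, 5), U(5, 30) and U(30, 60) for the
normal, mild–moderate and severe strata (default sizes 29/39/24). Default
recording length is 6 h (~72 epochs). The optional PPG renderer places one
asymmetric two-sided-Gaussian pulse (40 ms rise, 90 ms decay) at each beat
time for exercising the peak detector; peak-to-peak spacing equals the
interval series by construction.

What the generator does **not** emulate: motion artifacts and missed/spurious
beats, apnea-duration and hypopnea/apnea heterogeneity, sleep-stage
dependence, baroreflex dynamics and 1/f-like long-range correlation of real
HRV, or SpO2/respiration channels. Passing tests therefore demonstrate that
the pipeline computes its indices correctly and that the indices respond to
cyclic heart-rate variation of increasing density — not clinical screening
performance on real wearable data.

## Numerical and design choices

- Pattern catalogue: lexicographic over permutation tuples; stable sorts
  everywhere so tie behaviour is deterministic.
- Unobserved patterns are carried at probability 0 and ranked after observed
  ones by serial number; `T` is always the full class count.
- `0·log 0 = 0` throughout; σ = 0 falls back to uniform weights.
- Welch t-tests (unequal variances) for pairwise group comparisons; one-way
  ANOVA across the three groups; Pearson correlation with the conventional
  verbal strength bins (|R| in half-open 0.2-wide intervals).
- Screening: stratified 5-fold cross-validation at the recording level,
  severe class positive; confusion counts pooled over test folds and metrics
  computed from the pooled counts. Classifiers: decision tree (single tree),
  KNN (k = 5), random forest (100 trees), Gaussian naive Bayes. Undefined
  metric ratios (zero denominator) are NaN, never 0; F1 is 0 when precision
  and recall are defined but both vanish.
- Determinism: every stochastic component takes a seed; cohorts derive
  per-recording seeds from one root generator, and CLI runs with equal
  configuration and inputs are byte-identical.
- Interval files with a median value above 10 are auto-interpreted as
  milliseconds (wearable exports vary), with a logged notice.

## Problem sizes in the shipped checks

The test suite exercises the full 29/39/24 cohort at the default 6-h duration
for the severity-trend check (a few seconds of generation; the index itself
is cheap), 1000 random profile pairs per class count for the distance axioms,
200 replicates for the ANOVA type-I-error rate, and short (≤ 40 min)
recordings elsewhere. The worked example in the README is the only step that
takes minutes, dominated by per-epoch AR spectra.

## Known limitations

- The AR-spectrum band powers depend mildly on model order and grid density
  for nearly noiseless periodic tachograms; both are exposed as parameters.
- The peak detector is tuned for clean to moderately noisy pulse waveforms;
  heavily corrupted wearable segments should be excluded upstream.
- `recording_opibs` requires at least two usable epochs; very short or very
  sparse recordings are rejected rather than extrapolated.
- WFDB input requires the optional `wfdb` package at runtime; the reader
  fails with an informative message when it is absent.
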