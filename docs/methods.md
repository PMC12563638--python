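# Methods

This document records what the package computes, the parameter
defaults and why they are set that way, the numerical decisions taken
in the implementation, and the known limitations.

## Problem setting

EEG-based lie detection on the LieWaves protocol: 27 subjects, two
conditions (lie / truth), five channels (AF3, T7, PZ, T8, AF4), 25
trials of 3 s per condition, sampled at 128 Hz. Each trial-channel
series of 384 samples is summarized by complexity features; per-subject
classifiers separate the two conditions; the per-subject best channel
is tallied to find representative electrodes.

## Preprocessing

Recordings are DC-removed (mean subtraction per channel) and band-pass
filtered 0.5–45 Hz with a 4th-order zero-phase Butterworth filter
(`scipy.signal.sosfiltfilt`), then epoched into non-overlapping 3 s
trials; a trailing remainder shorter than one trial is discarded with a
warning. CSV is the native exchange format; EDF input is available via
the optional `mne` extra (values converted to microvolts).

## Fuzzy entropy (FE)

For a series `x` of length `N`, embedding windows of length `m` are
compared under the Chebyshev (max-coordinate) distance `d`, and each
ordered pair `i != j` contributes a fuzzy membership

```
mu(d) = exp(-d**n / r)
```

`phi_m` is the double average of memberships over pairs; FE is
`ln(phi_m) - ln(phi_{m+1})`. Defaults: `m = 2`, `n = 2`,
`r = 0.15 * sd(x)`; an absolute tolerance `r_abs` may override the
relative rule. Constant series (sd below 1e-12) are reported as
degenerate with FE 0; series shorter than `m + 2` samples raise
`ShortSeriesError` since no `m + 1` window pair exists.

The defaults are the standard fuzzy-entropy operating point for short
physiological series: `m = 2` keeps enough windows at 384 samples,
and `r = 0.15 * sd` sits in the flat region of the tolerance curve
where the estimate is stable against small tolerance changes (checked
by the monotonicity-in-`r` property test).

### Optimized path

The production path builds one shared `|x_i - x_j|` matrix and obtains
both `phi_m` and `phi_{m+1}` from running maxima over shifted diagonal
blocks, instead of re-embedding for each dimension. It is verified
against a literal triple-loop implementation to 1e-12 in the unit and
acceptance suites. An optional `baseline_removal` variant subtracts
each window's mean before comparison (the generic `cdist`-based path).

## Time-shifted multi-scale FE (TSMFE)

At scale `k`, the series splits into `k` interleaved subsequences
`x[j::k]` for `j = 0..k-1`; with 1-based offset `j` the `j`-th
subsequence has length `floor((N - j) / k) + 1`, and together they
partition the index set exactly (property-tested over random `N, k`).
FE is computed per subsequence with the tolerance taken from that
subsequence (a `tolerance_on="series"` switch uses the whole-series
tolerance instead) and averaged into `TSMFE_k`. Scales run to
`k_max = 10`; at 384 samples the scale-10 subsequences still hold ~39
samples. Subsequences shorter than `m + 2` contribute 0 and are
flagged. Scale 1 reduces exactly to plain FE.

## Hierarchical multi-band FE (HMFE)

A level-4 discrete wavelet transform with the `db4` wavelet decomposes
the trial into coefficients `[A4, D4, D3, D2, D1]`; each band is
reconstructed in isolation (all other coefficient arrays zeroed) and
scored with FE under a band-adaptive tolerance

```
r_band = (0.15 * sd(x)) * sd(band) / sd(x) = 0.15 * sd(band)
```

so quiet bands are not trivially "complex" merely because their
amplitude is small. Bands with `sd(band)/sd(x) < 1e-8` are reported as
silent (FE 0, flagged). At 128 Hz the five bands cover approximately
0–4, 4–8, 8–16, 16–32 and 32–64 Hz — delta, theta, alpha and the beta
range and above.

### Boundary handling

The transform uses **periodized** signal extension
(`mode="periodization"` in PyWavelets). This is the only mode in which
the orthogonal `db4` filter bank is exactly orthogonal on finite
signals, giving Parseval energy conservation to machine precision
(checked at 1e-8 for lengths divisible by `2**level`) and exact
additive band reconstruction (bands sum to the signal at 1e-8
relative). Symmetric extension would avoid wrap-around at the edges
but adds boundary coefficients that break both properties; since the
package's correctness checks rest on energy conservation and exact
band additivity, periodization is the deliberate choice. For
odd intermediate lengths the periodized transform pads internally, so
exact Parseval is only guaranteed for lengths divisible by
`2**level`; the protocol's 384-sample trials satisfy this at level 4.

## Features, classifiers, cross-validation

Each trial-channel contributes 16 features: `FE`, `TSMFE.1..10`, and
`HMFE.{A4,D4,D3,D2,D1}`; multi-channel matrices concatenate per-channel
blocks in the requested order. Standardization (z-scoring) is always
fit on the training fold only and applied to the test fold;
zero-variance training columns map to 0 with a warning.

Classifiers: C1 linear SVM (C=1), C2 RBF SVM (gamma="scale"), C3 3-NN,
C4 5-NN, C5 Gaussian naive Bayes, C6 LDA; the positive class is "lie".
Protocols:

- **LOOCV** — one fold per trial (50 folds per subject at the
  reference size); deterministic.
- **Stratified 10-fold** — seeded shuffle, class-stratified folds,
  accuracy pooled over folds.
- **LOSOCV** — every trial of one subject held out per fold, training
  on all other subjects; reports per-subject accuracies, their mean and
  sample SD.

Each runner audits its partition (every sample tested exactly once, no
train/test overlap). Report tables append `Mean` and `SD` rows (sample
SD, `ddof = 1`, rounded to 2 decimals).

## Channel selection

Per subject, the representative channel is the argmax of per-channel
accuracy, with ties broken in montage order (AF3, T7, PZ, T8, AF4);
occurrence counts over subjects summarize which electrodes carry the
discriminative signal.

## Published reference tables

The per-subject accuracy tables of the original LieWaves benchmark are
bundled as CSV under `fuzzent/data/` and exposed via
`fuzzent.reference`. The package's aggregation reproduces the printed
Mean/SD rows exactly at two decimals, with one caveat: three Mean cells
of the paired-channel table are truncations rather than roundings of
the per-subject means (printed 48.29 / 54.51 / 51.18 where the means
round to 48.30 / 54.52 / 51.19), so comparisons for that table allow
one unit in the last printed digit.

## Synthetic generator

`fuzzent.simulate` emulates the LieWaves layout: per-subject alpha
(~10 Hz) and theta (~5.5 Hz) oscillations with subject-level jitter,
plus 1/f ("pink") background noise shaped in the frequency domain.
Lie trials on the informative channels (default PZ and T7) receive
additional white noise with variance `effect_size` (default 0.4) times
the baseline variance — a *complexity* contrast, not a simple gain
change, since the amplitude-adaptive tolerance damps pure amplitude
effects. All randomness flows through a single seeded generator;
regeneration is bitwise reproducible. The generator matches the
protocol's shape (subjects, trials, channels, rates) but makes no
claim to physiological realism beyond the spectral mixture; its role
is to give the pipeline a ground truth for recovery tests.

Default problem sizes in tests and the acceptance script (20 subjects
for the end-to-end runs, 4 for unit fixtures) are package choices
balancing statistical resolution against runtime.

## Limitations

- **Amplitude-scale invariance does not hold at the default `n = 2`.**
  Under `x -> c*x`, Chebyshev distances scale by `c` and the relative
  tolerance `r = 0.15 * sd` also scales by `c`, so the exponent
  `-d**n / r` scales by `c**(n-1)`: the estimate is exactly invariant
  only for `n = 1`. The widespread informal claim that FE with a
  relative tolerance is scale-free is true for the `exp(-(d/r)**n)`
  membership family, but not for the `exp(-d**n / r)` form implemented
  here. The test suite asserts the true invariances (translation
  always; scale for `n = 1`) and keeps a deliberately failing check of
  strict invariance at the defaults
  (`tests/test_acceptance.py::test_amplitude_scale_invariance_of_entropy_stack`)
  so the property's absence stays visible. In practice the adaptive
  tolerance still strongly damps amplitude sensitivity; z-scoring
  inputs restores comparability across recordings of different gain.
- LOSOCV accuracy on real data is far below within-subject accuracy
  (64 % vs 83 % in the published tables), reflecting strong
  subject-specific signal structure; the synthetic generator reproduces
  the ordering but not the magnitude of that gap.
- The EDF reader requires the optional `mne` dependency and assumes
  channel labels matching the montage.
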