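# Methods

This note documents the models, numerical choices and limitations behind
`mibci`. It covers the synthetic data generators, the calibration and
streaming decoders, ERD/ERS mapping, protocol scoring and the pain-diary
statistics.

## Synthetic motor-imagery EEG

The generator emulates the phenomenology a sensorimotor BCI decodes, not
the biophysics that produces it.

**Model.** Each channel carries independent 1/f ("pink") background
noise (flat below 1 Hz), calibrated to a common RMS (default 10 µV).
Two rhythm sources sit at C3 and C4; each emits a mu (10 Hz) and a beta
(20 Hz) sinusoid whose total power equals `snr ×` the broadband noise
power at the source electrode (split equally between bands; default
`snr = 4`). Sources mix to neighboring electrodes with a Gaussian
kernel over great-circle scalp distance (width 0.35 rad), giving focal,
smooth topographies without a forward head model. Electrode positions
come from the idealized 10-05 layout bundled with MNE, projected to the
unit sphere; the desk-scale default montage is the 19-channel 10-20 set,
with 32- and 64-channel 10-10 variants.

**ERD.** During a cued trial, the source *contralateral* to the imagined
hand (C4 for left-hand imagery, C3 for right-hand) is scaled so its band
power drops by the factor `1 − erd_depth`; `relax` attenuates nothing.
The amplitude scale is therefore `sqrt(1 − erd_depth)`, and the
measurable task/rest band-power ratio at the source electrode is
`(1 − erd_depth)` diluted only by the in-band share of the pink noise
(≈ 8% of broadband power falls in 8–12 Hz), e.g. ≈ 0.61 at
`erd_depth = 0.4`, `snr = 4`.

**Phase structure.** Every burst segment (each trial and each
inter-trial gap) draws a fresh uniform phase per source and band. A
single phase per recording would make the two equal-frequency sources
mutually coherent, so the variance of mixed mid-scalp channels would
hinge on one arbitrary phase realization and a decoder could latch onto
it; per-burst phases emulate the incoherence of real hemispheric
rhythms and force the decoder to learn the power contrast. A mild
per-trial power jitter (gamma, mean 1, sd 0.05) adds trial-to-trial
variability while preserving the near-separable regime the calibration
benchmarks assume.

**Timing.** Default 256 Hz sampling (the amplifier rate is not dictated
by the protocol; configurable), 7-s trials separated by 2.5-s gaps so
both the 1–6 s calibration epoch and the −1…0 s ERD baseline fit.
Sessions are fully reproducible from the seed; identical seeds give
bit-identical recordings.

**What it does not model.** Volume-conducted broadband artifacts (a
single injectable high-variance contaminant exists solely to exercise
rejection), eye/EMG activity, nonstationary drifts, electrode noise
heterogeneity, and any realistic source geometry. Passing tests
therefore demonstrate the correctness of the pipeline's contracts on
signals with the right spectral/topographic structure — not clinical
performance on human EEG.

## Calibration decoder

**Filtering.** Hamming windowed-sinc FIR band-pass, cutoffs half a
transition width (2 Hz) outside the 8–30 Hz band, order from the Harris
approximation (3.3·fs/transition, odd; 423 taps at 256 Hz). Applied in
a single forward pass with group-delay compensation and reflection
padding: linear-phase, zero-lag, passband ripple ≪ 1 dB, > 40 dB down
by 6 and 35 Hz.

**Epoching.** The half-open span [cue+1 s, cue+6 s) is cut into 2-s
windows stepping 1 s (50% overlap): 4 windows per trial, labels and run
ids inherited from the cue. Trials that cannot contain the span are
skipped with a warning rather than crashing.

**Outlier rejection (stand-in).** The deployed system's rejection
statistic is unpublished, so a documented stand-in is used: per class
and channel, the log-variance of each window is scored with a
median/MAD robust z (0.6745·(x−med)/MAD); a window whose maximum score
across channels exceeds `z_max = 3.5` is excluded. When MAD = 0 the
standard deviation substitutes; when both vanish nothing is rejected
(identical windows can never be outlying). Rejection applies at
calibration only, never in the closed loop, and only removes — it never
edits or reorders windows. The rule is pluggable.

**CSP.** Per-class covariance is the average of per-window sample
covariances; a Ledoit-Wolf-style shrink toward the scaled identity
(γ = 0.1) engages when the condition number exceeds 1e8. For each class
the one-vs-rest generalized eigenproblem
`Σ_c w = λ (Σ_c + Σ_rest) w` is solved (`Σ_rest` = mean of the other
class covariances), eigenvalues in (0, 1) with 0.5 meaning no contrast;
components are ranked by extremeness `|2λ − 1|` and retained round-robin
across classes up to 6 components (near-collinear candidates are
skipped — the two problems of a 2-class set are mirror images).
Patterns are the pseudo-inverse of the filter matrix, so `W·A = I` on
the retained subspace.

**Features and LDA.** Features are `log var(w_j · x)` per component
(ddof = 1; constant windows floor at log 1e-12 with a warning).
Classification uses scikit-learn's pooled-covariance LDA (`lsqr`
solver), with `shrinkage="auto"` engaged when the pooled covariance is
ill-conditioned. Posterior columns follow the canonical class order
(relax, left_hand, right_hand); exact posterior ties resolve to the
lowest class index, deterministically.

**Cross-validation.** Folds are whole runs (series), k defaulting to
the run count — 9 for a competence test, 6 for a session calibration.
Overlapping windows of one trial share half their samples, so any
window-level split would leak; run-level folds cannot. CSP and LDA are
refit on training folds only. Accuracy is the fraction of correct
window decisions; a trial-level variant (majority over a trial's
windows) is available since the protocol's accuracy granularity is
ambiguous. The competence gate passes at mean accuracy ≥ 0.70
("reach" read as inclusive) and refuses a fourth attempt.

A corollary of the window correlation: under label permutation the
variance of CV accuracy is governed by the number of independent trials
(162), not windows (648), so chance-level checks use a binomial band at
the trial count.

## Streaming decoder

Decisions fall at `t = 2 s` and every 62.5 ms after — 16 per second of
signal, `floor((T − 2)/0.0625) + 1` in total. The published protocol
states both "overlap of 15/16" (a 125 ms step) and "62.5 ms, 16
decisions/s"; the 62.5 ms step is operative here (it defines the
user-visible rate and is stated twice), making the overlap 31/32; the
step is configurable.

Each decision's window is filtered with a *causal* short FIR (≈ fs/2
taps, same band, wider transitions) applied inside the window only, so
the decision at time *t* provably uses no sample after *t* (verified by
zeroing future samples). This trades a small spectral/phase mismatch
against the calibration filter for the latency contract; a
`mode="continuous"` flag instead zero-phase-filters the whole recording
for exact spectral parity in offline re-analysis. No decision smoothing
is applied by default; an optional majority-of-last-N post-filter
exists but is off, matching a protocol that describes none.

## ERD/ERS maps

Per trial of a task, the −1…6 s segment around the cue is analyzed with
a sliding DPSS multitaper: 0.5-s windows, 50% overlap, time-bandwidth 2,
3 tapers, 4–40 Hz grid — parameters chosen to resolve ≈ 2 Hz structure
across a 7-s epoch (the source analysis pins none of them). Power is
averaged across trials *first*, then normalized:
`100 · (P − B)/B`, with `B` the mean over baseline bins per channel and
frequency. Only spectrogram windows lying fully inside −1…0 s count as
baseline, so no post-cue samples contaminate it; by construction each
row's baseline bins mean exactly 0 and values are bounded below by
−100. Zero-baseline rows are masked (NaN), never infinite. The map is
invariant to overall amplitude scaling, and for a sinusoid whose
amplitude drops by factor *a* the band ERD approaches `100·(a² − 1)`.

## Protocol scoring

Exercise validation is dwell-based: each decoded label matching the
current segment's state contributes one decision step (62.5 ms) toward
its required hold; segments complete in order, and success requires the
final segment to complete within the allotted time. Cumulative dwell is
robust to the label flicker inherent to a 16 Hz stream; a stricter
consecutive-hold mode (dwell resets on a wrong label) is available.
The composite difficulty score is a declared stand-in assembled from
the two published ingredients: `n_states × (Σ holds / allotted time)` —
dimensionless, monotone in state count and temporal tightness, and
invariant to relabeling. The simulated course ramps +1 state every 3
sessions and +25% tightness every 2 sessions, recalibrates each session
on a reduced open-loop run (3 series × 3 trials/task), and scripts a
subject who holds each required state with 50% margin, holding the last
state until time expires.

## Pain-diary statistics

**Pain volume.** A day's paroxysmal burden is
`Σ episodes intensity × duration` in NRS·hours ("duration" is taken as
hours; the source unit is unstated). It is additive over episode sets
and zero for episode-free days.

**Synthetic diaries.** Per subject *i* and period *p*, daily volume is
`V = M₀ · mult_p · exp(b_i) · exp(ε)` with `b_i ~ N(0, subject_sd²)` a
log-scale random intercept and `ε ~ N(0, σ²)` log-normal day-to-day
dispersion (volumes are positive and right-skewed), so the period
median is exactly `M₀ · mult_p · exp(b_i)`. Episode counts are
1 + Poisson (a day with positive volume has at least one episode);
Dirichlet shares split the volume so episodes sum to it exactly.
Defaults (`M₀ = 335` NRS·h; multipliers 1/0.65/0.45/0.36/0.14 for
m-1/w1/w2/w3/w4; σ = 0.5; `subject_sd = 0.3`; 30 + 4×7 diary days)
mirror the magnitude of group-level median reductions such studies
report (≈ −35/−55/−64/−86% across the four weeks). NRS triplets always
satisfy min ≤ avg ≤ max.

**Period tables.** Quartiles of daily values per period, per patient
and pooled ("All"); percent variation is
`100·(median_p − median_baseline)/median_baseline`, rounded half-up to
2 decimals for printed-table parity (internal computation is full
precision), NA when the baseline median is 0. Packaged reference tables
(normalized: comma decimals converted, one patient's volume rows
carrying an ambiguity flag for an undecidable decimal/thousands
separator) support parity checks; flagged rows are excluded from them.

**Mixed models.** Group-level inference uses a random-intercept linear
mixed model (statsmodels MixedLM, REML) of the daily response on the
period factor with baseline as reference — phases m-1 / w1-w2 / w3-w4,
or the five-level weekly factor. The paroxysmal response is the daily
percent variation from the subject's own baseline median (so subjects
with very different absolute volumes are comparable); the continuous-
pain response is the raw daily average NRS. Wald z tests and
±1.96·SE confidence intervals accompany each contrast. The global
period test is a likelihood-ratio test of the period factor refitted
under ML, because an LRT on fixed effects is invalid under REML.
Per-patient contrasts use ordinary least squares with Wald t tests — a
single subject admits no random intercept — and a single-subject input
to the mixed fit redirects there with a warning. The long-term
follow-up period (weekly self-assessment) is summarized descriptively
and never modelled: the change of sampling cadence is a measurement
bias, not a treatment effect.

Two practical caveats established by the test suite: with literally
zero residual variance the REML random-intercept variance is not
identified (the profiled likelihood is flat) even though balanced fixed
effects remain exact; and the percent-variation response induces a
small genuine between-subject heterogeneity through each subject's
*estimated* baseline median, so the random-intercept variance collapses
to ~0 under `subject_sd = 0` only for raw-scale responses.

## Problem sizes

Desk-scale defaults keep every analysis fast while preserving the
protocol's structure: the benchmark session is the full competence-test
geometry (9 runs × 18 trials, 19 channels, 256 Hz, ≈ 24 min of signal);
unit tests use 3-run sessions on a 9-electrode montage; Monte-Carlo
checks use 60–200 seeds. These are the package's chosen operating
points and are all configurable upward.

## Known limitations

- The outlier-rejection rule and the difficulty formula are declared
  stand-ins for unpublished procedures; both are isolated and swappable.
- The causal streaming filter differs spectrally from the calibration
  filter; decoders dominated by content near the 8 or 30 Hz edges may
  shift slightly between offline and streaming decisions.
- EDF files are read (via MNE) but not written — the native container
  is a raw array + JSON sidecar, chosen for byte-determinism.
- Synthetic EEG realism is deliberately minimal (see above); clinical
  claims require real recordings.
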