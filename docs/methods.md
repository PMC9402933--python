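# Methods

## The task and its signals

The paradigm is a sustained-attention go/no-go task (SART) whose stimuli —
fixation cross, word, mask — flicker at 12.5 Hz (on/off every 80 ms at a
50 Hz refresh). A trial is: jittered flickering fixation (1480–2120 ms in
five steps), a 320 ms flickering word, an 880 ms flickering mask, then a
3020 ms blank inter-stimulus interval. Lowercase words require a key press
(Go, 8/9 of trials); uppercase words require withholding (Nogo, every ninth
trial here, 11.11%). Eight blocks of 90 trials each embed six thought
probes; a probe follows a Nogo trial and asks for thought content (options
1–6) and ratings of stickiness, self-focus and valence (1–9).

The flicker entrains a steady-state visual evoked potential (SSVEP) at
12.5 Hz and its 25 Hz harmonic, maximal occipitally (Oz). The scientific
question the pipeline serves is whether attentional state (on-task vs
mind-wandering) and thought stickiness modulate that entrainment — measured
as inter-trial coherence (ITC) and event-related spectral perturbation
(ERSP) — alongside classical markers (P1/N1/P3 amplitudes, posterior alpha
and frontal theta power, Go/Nogo behaviour), and whether those features
decode the state on single trials.

## Label derivation

Probe answers label the five trials preceding the probe (the probe's own
Nogo trial and the four before it). Content options are classified by their
meaning: *focused on the task* and *evaluating the task* → on-task;
*thinking about personal things* and *daydreaming / task-irrelevant
thoughts* → mind-wandering; *distracted by my environment* and *not
thinking about anything in particular* are excluded as unassignable.
Stickiness 1–4 → less sticky, 6–9 → more sticky; the midpoint 5 is excluded
because participants were instructed to use it when neither applied.
Trials outside every probe window are excluded from both labelings.

## Synthetic sessions

No recordings ship with the package; `synthgen` generates sessions with the
statistical structure the analyses assume. Per channel, the continuous
record is 1/f^β Gaussian noise (β = 1, sd 10 µV — a generic EEG background;
the FFT-shaped noise is padded to an FFT-friendly length and truncated).
Into each trial are added:

- an SSVEP drive: sinusoid at 12.5 Hz plus a 25 Hz harmonic (ratio 0.5 of
  the fundamental, amplitude 4 µV at Oz), both ramped by a 50 ms raised
  cosine over the 1200 ms word+mask window, with a *per-trial phase* drawn
  from a von-Mises distribution. The concentration κ is the generative
  counterpart of ITC: κ = 0 gives uniform phases (ITC → 0), κ = ∞ perfect
  locking. A square-wave on/off drive is available as an option; the
  two-sinusoid default makes the injected 12.5/25 Hz content analytically
  controllable, which is what the analyses read out.
- Gaussian-shaped ERP deflections: P1 (+5 µV, 120 ms, 25 ms half-width at
  half maximum), N1 (−5 µV, 170 ms, 30 ms), P3 (+6 µV, 400 ms, 80 ms),
  with fixed Gaussian scalp gain profiles centred on P7/P8 (P1/N1) and Pz
  (P3) computed from the BioSemi-32 montage geometry (spatial scale 5 cm).
  The electrodes of interest are given; the topographies around them are a
  modelling choice.
- alpha (10 Hz) and theta (6 Hz) oscillations with random phase per trial,
  posterior and frontal gain profiles respectively, active over
  −500..1300 ms around word onset with 100 ms ramps.

The latent state is the cross of attention × stickiness. It is drawn per
probe and held constant over the probe's five preceding trials (the label
window); unlabeled trials draw their state independently. Probe answers
follow the state, with two exclusion channels exercised at realistic rates:
19% of stickiness ratings are the excluded midpoint 5, and 20% of content
answers fall on the unassignable options. With an on-task prior of 0.52
this yields ≈ 42% on-task and ≈ 38% mind-wandering labels among probes,
matching the rates such studies report.

Default state parameters mirror the magnitudes the task is known to show:
phase concentration κ = 0.95 (less sticky) vs 0.80 (more sticky), which
lands measured fundamental ITC near 0.4 at the default signal-to-noise
ratio; posterior alpha 3.3 µV (mind-wandering) vs 3.0 µV (on-task); Nogo
accuracy 0.55–0.71 across the four states (less sticky and on-task more
accurate); Go response rate 0.99; RT ≈ 0.47–0.48 s (truncated normal,
floor 150 ms, sd 0.10 s). These contrasts are deliberately subtle — the
order the real phenomenon shows — so recovery tests inject explicitly
strong effects instead of relying on defaults.

What the generator does **not** emulate: ocular/muscle artifacts (beyond
what peak-to-peak rejection needs for testing), volume-conduction head
models, non-stationary drift, inter-individual topography differences, or
any coupling between behaviour and EEG beyond the shared latent state.
Passing tests therefore validate the *analysis chain* — its formulas,
windows, invariances and protocol hygiene — not claims about real brains.

## Preprocessing

Zero-phase 0.5–40 Hz band-pass (windowed-sinc FIR, Hamming, ~3.3 cycles of
the low edge; the symmetric kernel is applied centred by FFT convolution,
which is exactly zero-phase and O(n log n)); epoching −500..+4300 ms around
word onset (inclusive endpoints, onset sample owned by the epoch: length
floor(Δt·fs/1000)+1, i.e. 2458 samples at 512 Hz); baseline correction to
−500..0 ms; crop to −500..1300 ms (the analysis span; filters and wavelets
then keep their edges outside the 500–900 ms SSVEP window); automated
artifact rejection dropping any trial whose peak-to-peak amplitude exceeds
150 µV on any channel — a deterministic surrogate for manual inspection and
rater-based ICA, which synthetic data neither needs nor supports; average
re-referencing; and a final segmentation to −200..900 ms re-baselined on
−200..0 ms for the ERP analyses. The re-baseline window is the full
pre-stimulus segment of the crop. Labels are assigned after rejection, from
the probes alone.

## Feature extraction

**ERP peaks.** Condition averages are read out as window-restricted extrema:
max in 50–200 ms for P1 and 250–600 ms for P3, min in 100–250 ms for N1;
ties break to the earliest latency.

**Single-trial ERPs.** Each mean-removed −200..900 ms trial is
cross-covaried with unit-energy Ricker templates over the scale grid
{20, 40, 60, 80, 120, 160} ms (support ±4s), spanning brief P1 deflections
to the broad P3; the grid is a package choice. Within the component window,
local extrema of the component's polarity are collected across scales and
the largest |value| wins (ties: earliest time, then smallest scale); if no
extremum of the right polarity exists, the windowed global extremum is
returned flagged degenerate. Templates are matched per electrode listed in
the component specification. On noiseless self-matching the triple
(W, t, s) is recovered exactly; in 1/f noise the latency error grows with
template width — at a peak-to-noise-sd ratio of 2.5 the median error stays
under 20 ms for all three components, but for the broad P3 it reaches
~35–45 ms as the ratio approaches 1. This is an intrinsic cost of
single-trial estimation in a 350 ms search window, not a tuning issue.

**Band power.** Alpha (8–12 Hz) and theta (4–8 Hz) kernels are least-squares
FIRs on the grid {0, low·0.8, low, high, high·1.2, fs/2} with desired
response {0,0,1,1,0,0} (transition fraction 0.2) and order fs/low (64 and
128 taps at 512 Hz; bumped to an odd tap count for exact symmetry). The
kernel is applied zero-phase to the full −500..1300 ms epoch; the analytic
signal (Hilbert) is cropped to the pre- (−200..0 ms) or post-stimulus
(0..900 ms) interval and reduced by Welch's PSD (segment = half the
interval, 50% overlap, Hamming) to the square of the mean in-band PSD
magnitude. That squared-PSD reduction is reproduced deliberately as stated
by the source workflow even though conventional band power would stop at
the PSD; `mode="conventional"` provides mean |analytic|² instead. Both
intervals are produced and both enter the classifier by default.

**Time–frequency.** Complex Morlet coefficients at Oz on 8–30 Hz (0.5 Hz
steps), wavelet length interpolated linearly from 5 cycles at 8 Hz to
9.375 at 30 Hz (the two anchors are given; linearity between them is the
package's rule, configurable). ITC excludes exactly-zero coefficients from
a cell's mean and is clipped to [0, 1]. ERSP is absolute power in dB with
no baseline division: reported ERSP magnitudes in this paradigm (~48–52 dB)
are only compatible with an absolute measure, not a baseline-relative one
centred on 0 dB; all-zero cells floor at −300 dB. Summaries are inclusive
means over 12–13 Hz or 24.5–25.5 Hz × 500–900 ms.

## Decoding protocol

Rows are labeled trials; columns are the 18 single-trial-ERP features
(W, t, s × {P1@P7, P1@P8, N1@P7, N1@P8, P3@Fz, P3@Pz}), 16 band-power
features (2 bands × 4 electrodes × 2 intervals) and, in the with-SSVEP
variant, 2 per-trial ERSP band-window means (fundamental and harmonic).
The two variants differ only by those columns.

The protocol is reproduced literally: stratified 70/30 split; z-scoring of
the training and testing sets *each with its own column statistics* (the
stated procedure; it differs from the conventional train-statistics
transform, which remains available); 10-fold stratified grid search over 9
log-spaced values per parameter within C ∈ [10⁻⁵, 0.1] and σ ∈ [10⁻³, 10]
(the ranges and tune length are given, log spacing is the package's
choice; σ is sklearn's `gamma`), with minority-class duplication
oversampling applied inside each training fold only — never to validation
folds or the test set; ties in CV accuracy prefer smaller C then smaller σ.
The final model refits on the oversampled full training set and is scored
on the untouched test set (accuracy, sensitivity = TP/(TP+FN) on the
state of interest, specificity = TN/(TN+FP)). When the smaller class has
fewer members than the fold count, the fold count drops to it with a
warning rather than failing the participant.

Chance is corrected for test-set size: St(α) = binoinv(1−α, n, 1/c)·100/n,
the smallest accuracy significantly above guessing at level α. Note that
with imbalanced test sets a signal-free decoder converges to the majority
share (often ~0.6 here), which is why the corrected threshold — not a bare
50% — is the reference in all null checks.

## Statistics

Paired t on condition differences (sample sd, df = n−1); two-sided p.
Zero-variance differences return t = ±∞ with p = 0 (and infinite BF₁₀ —
the point null is excluded outright). The JZS Bayes factor is computed from
(t, n) only: the Cauchy(0, r) prior on standardized effect size (default
r = √2/2) is expanded as a normal scale mixture with
g ~ InverseGamma(1/2, r²/2) and the marginal-likelihood ratio integrated by
adaptive quadrature on a compactified variable (g = u/(1−u)), relative
tolerance 1e-10, with the likelihood ratio formed inside the integrand in
log space so large |t| cannot underflow. BF₁₀ < 0.3 supports the null,
> 3 the alternative, the closed interval [0.3, 3] is read as inconclusive
(boundaries inclusive by choice). No multiple-comparison correction is
applied by default, matching the source analysis; utilities for FDR can be
layered on by the user. Behavioural summaries: Go accuracy = response rate
on Go trials, Nogo accuracy = withhold rate, RT statistics over responded
Go trials only, cvRT = sample sd(RT)/mean(RT).

## Study orchestration

`run_study` spawns per-participant seeds from the study seed
(SeedSequence; recorded in every report), simulates, preprocesses,
extracts features once (the Morlet coefficients are shared between the two
classifier variants), decodes with and without the SSVEP columns using the
same split seed, and aggregates: group mean accuracies and a paired
t/BF comparison of the variants. Participants with an empty label class or
too few trials to split are excluded before classification and listed in
the result. Re-running with the same configuration and seed reproduces the
result exactly.

## Problem sizes in the test suite

The full task (8 × 90 trials, 32 channels) is simulated once to verify the
session layout; the cohort-level experiments run on scaled-down sessions —
2–4 blocks of 45 trials on an 8-electrode subset containing all analysis
channels — chosen so the suite exercises every property at meaningful
trial counts (60–120 labeled trials per participant, cohorts of 10–20)
while remaining quick. Direction- and recovery-experiments inject strong
contrasts (κ 4 vs 0.3, alpha 2 vs 8 µV) rather than the subtle defaults;
with default contrasts and these cohort sizes, single-participant
estimates are individually noisy by design, as the subtle real effects are.

## Known limitations

- The synthetic generator's realism limits (listed above) bound what green
  tests imply about real recordings.
- Single-trial P3 latency is intrinsically noisy near peak-to-noise 1
  (median error can reach ~40 ms); decoding uses W/t/s jointly, which is
  more robust than any one of them.
- ITC estimates from few trials are biased upward (the uniform-phase null
  is √(π/4n), not 0); condition contrasts on equal trial counts are
  unaffected, but unequal counts should be compared with care.
- The EDF/BDF path is read-only; continuous recordings are persisted in
  the package HDF5 container instead.
- The manual-ICA stage of lab workflows is deliberately replaced by a
  deterministic peak-to-peak criterion; real-data users should insert an
  ICA step between rejection and segmentation.
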