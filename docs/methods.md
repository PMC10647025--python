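# Methods

`ribecho` re-implements, as a tested library, a rib-detection pipeline for
a wearable single-channel pitch-catch ultrasound therapy device: the
device emits a short tone burst, records the reflected voltage on a
central receive channel, and must decide — without imaging — whether it is
sitting over an intercostal space, partially over a rib, or directly over
a rib. Because the original human recordings are not public, the package
ships a calibrated simulator so that every downstream stage (alignment,
feature extraction, four classifiers over three tasks, BMI-stratified
fitting, time-of-flight depth estimation) is exercised end to end.

## Signal model

A received trace `v(t)` sampled at `f_s = 25 MHz` for 160 µs is the sum of
three components:

* **Excitation artifact** — amplification and acoustic crosstalk produce a
  large waveform at stimulus time `t0`. It is modeled as a decaying
  715 kHz oscillation, `A_a · exp(-t/τ) · cos(2π f_c t)` with
  `τ = span/6`, gated to zero beyond its 15 µs span. Downstream it serves
  two roles only: its onset marks `t0`, and its span defines the interval
  every analysis window must exclude.
* **Rib echo** — a `k = 3`-cycle tone burst at `f_c = 715 kHz`
  (4.2 µs wide) under a Hann window, centered at the round-trip delay
  `t_e = 2d/c` for a rib at depth `d` (cm) with `c = 1480 m/s`, the speed
  of sound in water used as the soft-tissue approximation. Its amplitude
  follows a one-way attenuation of 0.8 dB/cm at 715 kHz over the
  round-trip path (`A_e = A_0 · 10^{-0.8·2d/20}`, default
  `A_0 = 10 V`), multiplied by 1 directly over a rib (locations C/E), by
  a per-trace draw from U(0.25, 0.65) partially over one (B/D), and by 0
  over the intercostal space (A).
* **Noise** — additive white Gaussian noise, σ = 0.05 V.

Centering the burst at the round-trip delay (rather than starting it
there) makes the envelope peak the time-of-flight marker, which keeps the
depth estimator's round trip exact up to the envelope smoothing width.

## Synthetic cohort

Twenty participants are drawn: 12 with BMI < 30 (low-BMI cohort) and 8 at
or above 30. Each anthropometric quantity (age, height, BMI, rib depth,
intercostal width) follows a truncated normal whose *underlying*
parameters are solved numerically so that the **truncated** distribution
reproduces the cohort's published mean exactly and its standard deviation
as closely as the bounded support allows (for very dispersed quantities
such as age the interval caps the attainable sd; the mean still matches).
Weight is derived as `BMI · (height/100)²` — height, weight and BMI cannot
be sampled independently. Rib depth and BMI are coupled through a Gaussian
copula (latent correlation 0.6) so deeper ribs co-occur with higher BMI
inside each cohort while both marginals keep their calibrated summaries.
Abdominal circumferences and body lengths are not published per cohort;
defaults are realistic values for each BMI range and exist to populate the
demographic feature block. Sex counts are fixed per cohort (6/12 male low,
2/8 male high).

Each participant contributes 10 repetitions at each of 5 locations
(A intercostal, B/D partial, C/E whole rib): 1000 traces. All randomness
flows from one master seed through spawned per-trace seeds, so a dataset
is bitwise reproducible.

## Preprocessing

`t0` is detected as the first sample within the opening 20 µs whose
absolute voltage reaches 50 % of the local maximum (the artifact dwarfs
everything else). Traces are re-indexed to `t0`, rectified (absolute
value), and analyzed in two windows chosen so that the published bin
counts and band edges are mutually consistent at 25 MHz:

* **time window [15, 107] µs** — 2300 samples: exactly 23 bins of 100
  samples (4 µs) and 11 bins of 200 samples (8 µs over the first 2200);
* **frequency window [15, 95] µs** — 2000 samples, zero-padded by its own
  length to 4000 points, giving a 6.25 kHz grid on which 10-sample
  (62.5 kHz) and 20-sample (125 kHz) bins tile [0, 1 MHz) without
  remainder and the retained band 493.8–931.3 kHz falls on grid edges.

Band limiting zeroes magnitudes outside the band but keeps the axis from
0 Hz, so bin indices stay global (715 kHz falls in 125 kHz bin 6).

## Features and scaling

The 70-entry vector is: 23 + 11 time-bin means, 16 + 8 frequency-bin
means, the 0 Hz magnitude (an average of the whole windowed signal), and
11 demographics (sex M→0/F→1, age, height, weight, BMI, three
circumferences, three lengths), in a fixed serialized order protected by a
schema hash. Every entry is divided by a per-group divisor and clipped to
[0, 1]. Defaults: 10 V for time features, 10³ V·samples for spectral
features, and per-demographic divisors (age 100, height 200, weight 150,
BMI 50, circumferences 150, lengths 100) inside the 40–200 range the
original protocol describes. The original device protocol scaled time
features by 10⁴ and frequency features by 10⁶ in its own (unreported)
acquisition units; applied to volt-scale traces those factors push all
informative features to ~10⁻⁴ while demographics stay O(1), after which
any L2-regularized linear fit discards the signal — so the defaults here
are calibrated to the simulator's units, and the protocol's factors remain
available as constants.

## Classifiers

Three tasks share the location→label mapping: Task 1 NoRib (A) vs
WholeRib (C/E, dropping B/D), Task 2 NoRib vs Rib (B–E pooled), Task 3
ternary NoRib/PartialRib/WholeRib.

**Threshold models.** The decision statistic is the maximum of the
rectified signal in a time window, or the maximum spectral magnitude in
the fixed 493.8–931.3 kHz band. For a candidate threshold θ the rule is
`s ≥ θ → positive`; the fitted θ is the exact minimizer of balanced error
(1 − mean per-class recall) over midpoints of consecutive distinct
statistics plus one candidate below the minimum and one above the maximum
(ties → smallest θ). The time window is fitted by iterative range
reduction: a full (start, end) grid scan at 8 µs resolution over
[15 µs, trace end], then two local refinement rounds with the step halved
each time; ties prefer the shorter, earlier window. Task 3 freezes θ₁
from the Task 2 fit on the same cohort and fits θ₂ > θ₁ on the Rib-class
traces only, so the second threshold always exceeds the first by
construction. Windowed-max was chosen as the statistic because it is
monotone in echo strength and robust to where the echo falls inside the
window.

**Linear models.** Logistic regression minimizes mean deviance loss
`log(1+exp(-y f))` with an L2 penalty λ = 1/n; the linear SVM minimizes
mean hinge loss with λ = 1/(C·n), C = 1, equivalent to the usual
box-constraint form. Both run a deterministic quasi-Newton solver from a
zero start (gradient tolerance 10⁻⁸, 10⁴ iteration cap; the hinge's
non-smooth kink makes that stopping test advisory for the SVM), so fits
are order-invariant and reproducible without a seed. Classes are balanced
by seeded undersampling to the minority count before fitting. The ternary
task uses a one-vs-one ensemble of three pairwise models with
majority-vote decoding; ties go to the class with the largest summed
absolute margin. A score of exactly 0 is the positive class. Reduced
models retrain on the top-k features ranked by the |weight| of a full
logistic fit (averaged over the three pairwise fits in the ternary case)
— a deliberately simple stand-in for the original study's unpublished
selection procedure.

## Evaluation protocol

Balanced accuracy is the unweighted mean of per-class recalls; binary F1
takes Rib/WholeRib as positive, ternary scores use macro-F1; F1 is 0 when
precision+recall degenerates. Train/test splits are stratified by class
at the signal level under a seed (80/20 by default). Splitting at the
signal level means repetitions of one participant can appear on both
sides; the study protocol does not state grouping, and the per-participant
alternative is available by filtering traces before splitting. K-fold
cross-validation assigns folds by a stratified round-robin whose cursor
carries across classes, so folds differ by at most one sample and k = n
reduces exactly to leave-one-out.

## Depth estimation

The echo is localized at the maximum of a centered-moving-average envelope
(105 samples ≈ 3 carrier periods) after blanking the artifact span plus
the smoothing half-width; depth is `c·t/2` in cm. A trace whose
post-blanking envelope peak does not clear 3× the noise floor (median
envelope over the final 10 µs) is reported as echo-free rather than given
a depth. Localizing the peak (not the onset) pairs with the simulator's
burst centering; the smoothing half-width (±2.1 µs ≈ 0.16 cm) bounds the
intrinsic accuracy. BMI and the circumference-to-height (C/H) ratio are
computed per participant and correlated with depth in the depth report.

## Problem sizes and numerical choices

The default study (20 participants × 5 locations × 10 reps = 1000 traces)
simulates in ~5 s and a full 4-method × 3-task × 3-cohort benchmark runs
in under a minute on one core. Replicated experiments (threshold-recovery,
stratified-vs-pooled) use 50 and 10 seeded replicate studies with 4
repetitions per location, enough for stable means at test runtime.
Thresholds are compared with a 10⁻¹² tie tolerance so floating-point
rounding cannot reorder mathematically tied candidates. Degenerate inputs
fail loudly: single-class threshold fits, windows outside the trace,
spectra at the wrong resolution, schema-hash mismatches between features
and models.

## What the simulator does and does not show

Passing tests demonstrate that the pipeline's machinery is correct on
signals with the study's published statistical structure — not that the
published human accuracies transfer. Known gaps between simulation and
reality:

* **Shallow ribs are invisible by construction.** A rib shallower than
  ~1.15 cm echoes inside the 15 µs artifact span, and every analysis
  window starts after it; the low-BMI cohort (depth 1.4 ± 0.7 cm) draws a
  sizeable fraction of such participants, capping its attainable accuracy
  below the published 100 %. Real echoes presumably remained detectable
  through ringdown and superposition effects not modeled here.
* **Stratification is cost-free, not advantageous.** The published gain
  from BMI-stratified thresholds is attributed to participant-dependent
  clutter and artifact leakage into wide windows; with a hard-gated
  artifact and homogeneous white noise, pooled and per-cohort models are
  both near-optimal, and the replicated comparison shows stratification
  "does not hurt" rather than a large win.
* No tissue-layer reverberation, no beam steering, no per-participant
  receive-gain variation; the absolute voltage scale is a calibration
  choice (echo amplitudes of a few volts, matching the plausible range of
  the published fitted thresholds, 1.4–5.3 V).
* The published real-data depth error (median 0.52 cm) reflects imaging
  ground truth and tissue heterogeneity; the simulator's round trip is
  exact up to envelope smoothing, so its median error is near zero by
  design.
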