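# Methods

`gazedyn` implements a closed-set biometric identification pipeline for
eye-movement recordings from a jumping-point experiment, together with a
synthetic-data generator that emulates the recording protocol so the whole
method can be exercised and validated without human data.

## The recording protocol and its forced counts

A point is shown at 29 screen locations (the 9th and 29th coincide), 3 s
each, with gaze sampled at 1000 Hz in two sessions per subject.  For each
stimulus point only the first 1000 samples after onset are analysed — a
window that spans the saccadic latency, the saccade itself and the start
of the new fixation — and cut into ten non-overlapping 100-sample
segments.  These protocol numbers force all the set sizes the pipeline
reproduces: 24 subjects × 2 sessions = 48 recordings; 10 segments × 23
features = 230 values per one-point vector; 24 × 2 × 29 = 1392 one-point
vectors splitting 1044/348 at 75%; stride-1 windows of three consecutive
points give 27 vectors per subject-session, 1296 in total, splitting
972/324.

## Features (23 per segment)

* **Kinematics (16).** Horizontal and vertical velocity by forward
  differencing (99 values per segment; deg/s), resultant velocity
  `sqrt(vx² + vy²)`, and resultant acceleration (forward difference of
  resultant velocity; deg/s²).  For each of the four series: max, min,
  mean, and range = max − min.
* **Spectrum (6).** The discrete Fourier transform
  `z[n] = Σ_k x[k]·exp(−i2πkn/N)` of the horizontal-velocity series; the
  first six values are kept.  By default the *real parts* of `z[0..5]` are
  used; a `dft_mode="magnitude"` switch returns `|z[0..5]|` instead, since
  either reading of "the first values of the transform" is defensible.
* **Largest Lyapunov exponent (1).** Computed on the horizontal-velocity
  series, treating the oculomotor plant as a nonlinear dynamical system.

## Lyapunov estimation

The series is delay-embedded, `y_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ})`,
giving `M = N − (m−1)τ` states.  The lag τ is the first local minimum of
average mutual information (16 equal-width histogram bins); a minimum is
only accepted when the AMI profile has non-trivial range (> 0.05 nat),
because on white noise the estimate fluctuates and would otherwise
produce a spurious minimum — structureless profiles fall back to τ = 1.
The dimension m comes from the false-nearest-neighbours criterion
(distance-ratio tolerance 10, acceptance threshold 1% false neighbours).

Each state's nearest neighbour within radius ε = 10% of the series
amplitude — outside a Theiler window of τ samples — is tracked forward,
and the mean log separation ⟨ln d_j(i)⟩ is recorded per evolution step.
The exponent is the least-squares slope of that divergence curve against
`i·Δt` over its initial linear region: the fit stops once the curve has
climbed 75% of its total rise, because beyond that point pairs saturate at
the attractor size and the local slope no longer reflects the exponent
(with < 1 nat of total rise the whole curve is used — the flat curve of a
non-chaotic signal).  Degenerate inputs (constant series, no neighbour
pairs, infeasible embedding) return a flagged sentinel mapped to 0.0 with
a per-segment validity bit, so feature vectors stay NaN-free.

Two numerical floors matter in practice.  Exactly periodic series produce
float-coincident states whose distance ratios are pure rounding noise;
both the FNN criterion and the neighbour search therefore ignore pairs
closer than 10⁻⁸ of the series amplitude.  And validation signals use
incommensurate periods — a sine whose period exactly divides the sample
count visits only a handful of distinct states, a degenerate case no
physical recording exhibits.

Per 100-sample segment the estimator runs with τ ≤ 5, m ≤ 4 and 10
evolution steps; these series are too short for a precise exponent, and
the value is used as a discriminative feature, not an absolute estimate.
On long series the estimator is accurate: on the r = 4 logistic map
(N = 5000) it recovers ln 2 to within a few 10⁻³ (checked against the
orbit average of ln|4(1 − 2x)|), and pure sinusoids yield ≈ 0.

## Synthetic subjects

A simulated subject is a bundle of oculomotor parameters drawn from
physiological ranges: peak saccadic velocity of a 10° jump ∈ [300, 500]
deg/s; saccadic latency with per-subject mean ∈ [140, 260] ms and
within-subject sd ∈ [15, 25] ms, truncated to [80, 400] ms; microsaccades
at 1–2 Hz with amplitude ∈ [0.15, 0.4]° and peak speed ∈ [15, 50] deg/s;
drift with mean speed ∈ [0.3, 0.7] deg/s bounded below 0.13°; tremor with
amplitude ∈ [1.0, 2.5]·10⁻⁴ ° (bracketing the nominal 1.7·10⁻⁴) and
frequency ∈ [40, 100] Hz; and a per-recording noise scale ∈ [0.1, 1] of a
10⁻⁴ ° white measurement floor — recording-noise idiosyncrasy is itself a
documented identity cue in this field.

Design choices where the literature leaves latitude:

* **Saccade waveform.** Minimum-jerk profile; the peak-velocity/duration
  pair is tied through `v_peak = 1.875·A/D`, with duration set so peak
  velocity follows a saturating main sequence `v(A) ∝ 1 − exp(−A/6°)`
  anchored at the subject's 10°-jump parameter.  Drawing velocity and
  duration independently would contradict the smooth-waveform constraint.
* **Undershoot and correction.**  Primary saccades undershoot with a
  population gain of 0.92; jumps ≥ 1° are followed by a corrective saccade
  after an intersaccadic latency of 0.75 × the subject's latency mean
  (same sd).  Both behaviours are textbook oculomotor phenomena and give
  each trial a second velocity burst whose size and timing carry subject
  identity, as real recordings do.
* **Drift model.**  Ornstein–Uhlenbeck *position* process whose
  sample-to-sample velocity is broadband with RMS set by the subject's
  drift speed.  A smoother integrated-OU-velocity variant (low-pass drift)
  was evaluated and rejected: at 100 ms segment scale it leaves only ~1
  independent speed sample per segment, destroying the drift-speed readout
  that the broadband model provides, without changing any protocol-level
  property the pipeline measures.
* **Cohort sampling.**  The 24 subjects are drawn on a maximin
  Latin-hypercube over the parameter ranges rather than iid: iid draws
  intermittently produce two near-identical subjects, which makes a
  closed-set identification experiment meaningless rather than hard.  The
  stratified design guarantees the cohort spreads across parameter space
  while every subject remains inside the physiological ranges.
* **Stimulus layout.**  28 unique points on a jittered 7 × 4 grid over a
  40° × 32° field (horizontal × vertical; the stated screen geometry —
  370 mm wide at 500 mm — implies ~40° horizontally), presented in a
  seeded random order, with the 29th position repeating the 9th.
* **Session effect.**  A drift factor d perturbs each generative parameter
  multiplicatively for sessions after the first (`p′ = p·(1 + d·η)`,
  η ~ N(0, 0.15), clipped to the physiological range).  d = 0 by default:
  sessions then differ only in their noise streams.

### What the generator does and does not emulate

It reproduces the protocol structure, the saccade main sequence, latency
variability, undershoot/correction, and the three fixational
micromovements with subject-specific parameters.  It does *not* emulate
blink artifacts, pupil-size coupling, head-motion residuals, calibration
drift, attention lapses, or the rich waveform idiosyncrasies of real eye
movements.  Passing the recovery tests therefore shows the pipeline can
identify subjects whose signals differ in these physiological parameters
under the stated protocol — it does not certify the accuracy levels
reachable on human recordings, which are reported only for the authors'
private dataset.

## Classification and evaluation

Four classifiers (scikit-learn): kNN with Euclidean metric (k = 5 default,
7 available), a CART decision tree, a 100-tree random forest whose
prediction averages per-tree class probabilities, and Gaussian naive
Bayes.  No feature scaling is applied by default.  Splits: per-subject
stratified 75/25 (seeded, disjoint; `train_test_split` with `stratify`)
and session-disjoint (train on session 1, test on session 2).  Per-vector
evaluation: accuracy, per-class sensitivity/specificity/precision/F1 from
the confusion matrix — precision and F1 are flagged *undefined* (excluded
from macro averages, with an exclusion count) when a class is never
predicted — and one-vs-rest macro ROC/AUC (per-class AUCs averaged
unweighted; the macro ROC curve interpolates TPR onto a shared FPR grid).
Subject-level identification takes the majority vote over each subject's
test-vector predictions, ties broken toward the smallest label; results
are aggregated as mean ± sd over 10 seeded repetitions.

## Problem sizes and determinism

The default experiment (24 × 2 × 29 points, 13920 segments) extracts in
tens of seconds on one core; tests and the acceptance script run the full
protocol rather than a scaled-down version, plus two extra drifted
datasets for the session-effect probe.  Every stage is a pure function of
its inputs and seeds: dataset seeds derive from one master seed, split
seeds are explicit, and forest/tree randomness is seeded per repeat, so
reports are bit-reproducible.

## Known limitations

* Per-segment exponents on 99-sample series are feature-grade, not
  physical estimates; their sign and magnitude depend on the capped
  embedding settings.
* Overlapping three-point windows share underlying points between train
  and test under the mixed-session split (vectors are distinct; their
  source segments partially overlap).  This mirrors the stated
  set-construction procedure and is flagged here rather than altered.
* The AMI lag on strongly periodic signals sits in a flat trough around
  the quarter period; any lag inside the trough is equally defensible.
* `k = 7` for kNN and `dft_mode="magnitude"` are exposed but not part of
  the default evaluation.
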