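# Methods

This note documents the models, numerical choices, and open design
decisions behind flankerlab, and what the synthetic-data tests do and
do not establish about real recordings.

## Stimulus schedule

The session is 10 mini-blocks × 24 trials (1 s pitch: 250 ms stimulus,
750 ms ISI), preceded by two 10-trial training blocks that are flagged
and excluded from every analysis.  Half of the blocks are mainly
congruent (18 congruent + 6 incongruent), half the reverse; left/right
targets are balanced 12/12 per block and — stricter than the block-level
balance alone — 9/9 within the majority class and 3/3 within the
minority class, which is what makes the session-level 60-per-cell
balance exact.  Inter-block intervals are drawn uniformly on [6, 14] s
(mean 10 s, matching both stated moments; whether the original
intervals were uniform or a fixed list is unknowable, and uniform is
the maximum-entropy choice consistent with them).

Constraint satisfaction: the 18/6 congruency mixture under the
"maximally three in a row" rule is a rare event under random shuffling
(acceptance well below 1e-4 per shuffle), so plain rejection sampling
is hopeless.  Within-block congruency orders are instead drawn by
constrained sequential sampling: at each position a label is a
candidate only if an exact feasibility test shows the remaining counts
can still be packed into runs of ≤ 3, and a candidate is chosen
uniformly.  This always terminates, is deterministic given the seed,
and is validated against the same rule-based validator used for
external schedules (generator and validator cannot drift apart).  The
sampler is not uniform over all admissible sequences — no analysis here
depends on that — and target directions within each congruency class
keep classic rejection sampling (balanced shuffles retried against the
run rule).  A design that is outright unsatisfiable (e.g. 100% one
condition) raises after the retry cap rather than silently violating a
rule.  Four canonical pseudorandomized versions existed in the original
setting but were never published; any seed yields a valid version here.

## Behavioral scoring

Only the first response inside the 1000 ms trial window counts; a trial
without a response is *missing*, never an error.  Accuracy is the
percentage of correct trials with all presented trials in the
denominator (missing trials presented-but-unanswered); an alternative
excluding missings is available as a flag, since "percentage of
correctly answered trials" does not fix the denominator.  Mean RTs are
computed per subject over correct trials, then averaged across subjects
— the level at which the repeated-measures ANOVA operates.  Only
correct trials are passed on to the EEG stage.

## EEG pipeline

* **Filters.**  "12 dB/oct" is read as 6 dB/oct per pole: a 2nd-order
  Butterworth low-pass at 50 Hz applied forward–backward (zero phase,
  so the effective magnitude is |H|²).  The notch is a 4th-order
  band-stop, 50 ± 2 Hz — 50 Hz mains for a European recording site.
* **Epochs.**  −300…1000 ms around stimulus onset (1301 samples at
  1000 Hz), onset sample inclusive; all windows are half-open [a, b).
* **Ocular correction** (Gratton–Coles): the condition-average ERP is
  subtracted from each epoch and from the EOG; per-channel propagation
  coefficients are estimated by least squares on the pooled residuals;
  coefficient × raw EOG is subtracted from the raw epochs, which leaves
  the stimulus-locked ERP in place.  Vertical EOG (FP2) is the primary
  regressor; horizontal (F10) can be added as a joint second regressor
  but is off by default, since only vertical artifacts are the stated
  target.  Zero-variance EOG yields zero coefficients and a warning
  path, not a crash.
* **Artifact rejection** replaces manual visual inspection (whose
  thresholds are unrecoverable) with explicit per-epoch-per-channel
  rules: |x| > 100 µV, peak-to-peak > 150 µV, gradient > 50 µV/ms —
  all configurable, and the mask is monotone (never un-rejects).
* **Inclusion gate.**  Cutoff = ⌈total-per-condition / 3⌉ (120 → 40);
  a subject stays only if every condition retains at least that many
  segments on ≥ 15 of the 29 scalp electrodes.
* **Baseline/re-reference.**  Mean of [−100, 0) ms subtracted per
  epoch and channel, then the average of TP9/TP10 subtracted from all
  non-mastoid channels.  Both are linear and commute.

## ERP window statistics

Thirty-five 20 ms windows tile [0, 700) ms.  Per group and electrode,
subject-wise window means are compared between conditions with paired
t-tests at two-sided α = 0.05, uncorrected — the cluster rule is the
multiplicity control.  A cluster is a maximal run of ≥ 2 consecutive
significant windows with ≥ 2 electrodes significant in *all* windows of
the run (the strictest reading of the co-occurrence rule); cluster
spans from the two groups are unioned into the analysis windows
(whether the original analysis unioned or intersected groups is not
stated; union is implemented and flagged here).  Peak measures take the
extremum of the stated polarity, earliest sample on ties.  Window
ANOVAs are congruency × electrode × group; interactions involving
congruency trigger per-electrode post-hoc paired t-tests with BH-FDR
over the 29-electrode family of that window.

## Statistics kernel

The mixed-design repeated-measures ANOVA uses the orthonormal-contrast
formulation: for each within effect, an orthonormal contrast matrix
(Helmert, Kronecker products for two factors) maps cell vectors to
contrast scores, and the classical sums of squares become one-way
ANOVA sums of squares of those scores accumulated over columns.  With
unbalanced groups the within-effect term uses unweighted group means
(Type-III convention); balanced designs coincide with the classical
formulas to machine precision.  Greenhouse–Geisser
ε = (tr S)²/(q · tr S²) comes from the pooled within-group covariance
of the contrast scores, bounded to [1/q, 1]; a two-level factor forces
ε = 1 and no correction.  Mauchly's W uses the eigenvalues of that
covariance with Box's chi-square approximation including the
second-order series term; a singular covariance returns W = 0, p = 0 by
convention.  The correction triggers at Mauchly p ≤ 0.05, consistent
with the global α.  Three-way designs are computed as 2-within ×
1-between with per-effect sphericity handling.  BH-FDR is the step-up
cumulative-minimum construction, capped at 1.  Sums of squares below a
data-scale-relative tolerance (100·eps·n·cells·max²) are treated as
exact zeros so that identical conditions report F = 0 rather than a
ratio of rounding noise.

## fNIRS pipeline

Optical densities are ΔOD = −log₁₀(I/I₀) with I₀ the whole-record
channel mean (first-minute mean available as a config alternative; the
choice only shifts the intercept).  The 2 × 2 Beer–Lambert system is
solved per sample with compiled molar extinction coefficients
(cm⁻¹ per mmol/l: 760 nm — HbO 0.586, HbR 1.5485; 850 nm — HbO 1.058,
HbR 0.6913) and adult-head differential pathlength factors (7.25 /
6.38), interoptode distance 3.5 cm; these device-dependent constants
are configurable and echoed into output metadata.  Concentrations are
reported in µmol/l (the natural magnitude for these signals; the
conversion to other concentration units is a constant factor).
Artifact spans — supplied or auto-detected where the first difference
exceeds 6 MAD-based robust standard deviations — are replaced by linear
interpolation between span edges (edge spans hold the nearest value).
The 0.4 Hz 3rd-order Butterworth low-pass is applied forward–backward.

The GLM design holds one 24 s boxcar per mini-block, labeled by block
type, convolved with a canonical double-gamma HRF (undershoot ratio
1/6) time-scaled so its mode sits exactly at 5 s, unit peak.  Two
condition regressors plus intercept is the default reading of the
ambiguous "predictor including both conditions"; a single combined
task regressor is available via `combined=True`.  Condition assignment
is at block level (mainly congruent vs mainly incongruent) because the
analysis is mini-block-wise; the 75/25 mixture inside blocks is exactly
what the generator reproduces, and it blurs single-trial condition
differences by construction.  OLS per channel and chromophore; oxy- and
deoxyhemoglobin are analyzed separately, and an activation is coupled
(HbO up, HbR down) in the generator, a relation the pipeline preserves.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

* Behavioral: lognormal RTs with condition means 368.18 / 410.27 ms
  (sd 60 ms), truncated below at 100 ms; draws beyond 1000 ms become
  missing trials.  Condition accuracies 96.84 / 87.35%.  Subject-level
  random effects: RT shift sd 20 ms, condition-difference sd 5 ms,
  accuracy logit shift sd 0.3.
* ERP templates: a Gaussian negativity (σ 12 ms) at the six right
  centro-parietal electrodes C4, CP4, CPP6H, P4, P8, Pz, latencies
  275 / 277 ms, amplitudes −2.0 / −3.5 µV (congruent / incongruent);
  a broad posterior positivity (σ 35 ms), latencies 385 / 421 ms,
  amplitudes 8.0 / 6.4 µV, with a front-to-back topography ramp.
  The negativity amplitudes are calibrated so the sliding-window
  procedure detects the 260–300 ms cluster at reduced cohort sizes;
  they are *not* a claim about the physiological microvolt values,
  which the source results do not report.  Subject random effects:
  lognormal amplitude scale (sd 0.2) and a shared ±8 ms latency shift.
* EEG background: spectrally shaped 1/f noise (8 µV sd), plus ongoing
  alpha modeled as 9–11 Hz band-passed noise (3 µV amplitude scale,
  posterior-weighted).  Alpha must be narrowband noise, not a rigid
  sinusoid: a 10 Hz sinusoid is phase-locked to the exact 1 s trial
  pitch, survives averaging, and biases peak latencies — real ongoing
  alpha dephases within about a second.  Blinks arrive as a Poisson
  process (15/min, 150 µV, σ 50 ms) on FP2 and propagate to the scalp
  with coefficients decaying front to back; occasional 400 µV spikes
  (1% of trials) exercise the rejection stage.  TP9 is identically zero
  (online reference).
* fNIRS: the exact forward Beer–Lambert image of HRF-convolved block
  activations with HbO betas 0.5 / 0.8 µmol/l (mainly congruent /
  mainly incongruent) and HbR = −HbO/3, plus cardiac (~1.1 Hz), Mayer
  wave (0.1 Hz), linear drift, and white noise in OD space; intensities
  are I₀·10^(−OD) with random per-channel baselines.

What passing tests show — and what they do not: noiseless runs prove
the pipeline's algebra (template identity, Beer–Lambert round trips to
1e-10, exact GLM betas); noisy cohorts prove statistical recovery of
injected effects at realistic SNR and that the ANOVA chain is
calibrated under the null.  The generator does not model volume
conduction beyond fixed mixing coefficients, heteroscedastic or
non-stationary noise, motion artifacts in EEG, fNIRS motion beyond
step/spike injection, or any dependence of behavior on the EEG state,
so the tests cannot certify performance on pathological real-world
recordings — only that the implementation does what its definitions
say.

## Problem sizes

The validation suite runs a 20 + 20-subject cohort with full-length
240-trial sessions for parameter recovery (the original cohort was
28 + 29; halving the groups keeps every recovery interval comfortably
tight at a few minutes of compute), 500 measure-level null replicates
for the behavioral calibration and 200 each for the ERP and fNIRS
calibrations, with rejection rates judged against the exact binomial
95% band around α = 0.05.  The analysis drivers use still smaller
cohorts (5–6 per group) as narrative examples.

## Known limitations

* The within-effect convention under unbalanced groups (unweighted
  means) matches SPSS-style Type III; other packages use weighted
  means, so unbalanced within-effect F values can differ legitimately.
* Error-related analyses are out of scope by design (error rates in
  this paradigm are too small to average), as are ICA-based artifact
  removal, channel interpolation, source localization, time–frequency
  analysis, and short-separation fNIRS regression.
* The peak-latency estimator is the raw extremum; with overlapping
  components (the negativity's tail under the positivity's flank) it
  is slightly biased at electrodes carrying both, which is why latency
  recovery is evaluated at a posterior electrode outside the negativity
  set.
* BrainVision support covers multiplexed INT_16 and IEEE_FLOAT_32 —
  the variants this workflow produces and consumes — not vectorized
  orientation or INT_32.
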