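# Methods

`mindwander` implements an offline, user-independent detector of
mind-wandering episodes during paragraph-by-paragraph reading, driven by two
wearable-grade sensors — a 90 Hz consumer eye tracker and a 4 Hz wrist
electrodermal activity (EDA) sensor — together with the repeated-measures
behavioral analysis of the underlying 3 × 3 (text type × music type) reading
design. Because no dataset accompanies the design, the package includes a
first-class synthetic-session generator with complete ground truth; all
quantitative claims in the test suite are statements about recovery of that
ground truth, not about any real recording.

## Study model

A *study* contains participants, each completing two sessions (one with sad,
one with happy background music, order counterbalanced). A session presents
24 reading segments: 2 texts × 3 text types (computer science, psychology,
random topic) × 4 paragraphs, with music playing on exactly 12 of the 24
paragraphs, balanced within text type against the no-music control. Mind
wandering is labeled per paragraph by the self-caught method: a label of 1
means at least one button press fell inside the paragraph's half-open
interval `[onset, offset)`. All intervals in the package are half-open and
all times are milliseconds from session start, which makes the 90 Hz and
4 Hz streams joinable without boundary ambiguity.

## Gaze pipeline

Fixations are detected with the dispersion-threshold identification (I-DT)
algorithm: grow a sample window while `(max x − min x) + (max y − min y)`
stays within a threshold, and emit a fixation when the window spans at least
a minimum duration. Defaults are 40 px (≈1° of visual angle at 60 cm on a
1920 × 1200 monitor) and 100 ms. Invalid samples are dropped before
detection, and an inter-sample gap above 75 ms splits the window so a
fixation can never span a blink or tracking loss. The implementation is
verified sample-for-sample against an exhaustive window-enumeration
reference on randomized streams.

Saccades are consecutive-fixation transitions: Euclidean centroid distance,
transit time (`next.onset − prev.offset`), and angle `atan2(Δy, Δx)`. A
*regression* is a leftward saccade that stays within one line height
(36 px); leftward sweeps that also descend a line are line returns and are
not counted. Pupil size is z-scored per participant across both sessions
(per-session scoring was the alternative; per-participant pooling preserves
between-session arousal differences, which is what the detector should see).

The eye feature registry has 19 values per paragraph: the mean of all nine
base measures (fixation duration, pupil size, saccade length, saccade
transit time, saccade angle, regression length, and the three counts) plus
min and max for five of them (fixation duration, pupil size, saccade
length, saccade transit time, regression length). "Saccade velocity" is
defined in the registry as the transit time in milliseconds — a duration,
despite the name — and is implemented exactly so; a px/ms rate can be
derived but is not part of the default registry. Regression-length
statistics are taken over regressions only and are zero for
regression-free paragraphs. Paragraphs are excluded when fewer than 75% of
samples carry a valid tracking flag or fewer than 5 fixations survive the
reading-area filter; an excluded paragraph is dropped from *every*
modality, not just the eye model.

## EDA pipeline

The skin-conductance signal is modeled as

    sc(t) = tonic(t) + (B ∗ p)(t) + ε(t),     B(t) = e^(−t/τ0) − e^(−t/τ1)

with τ0 = 2.0 s, τ1 = 0.7 s, a non-negative sparse sudomotor driver `p`, and
a slowly drifting tonic level. After per-subject z-standardization (pooled
over both sessions, population SD) the decomposition solves the convex
program

    min_{p ≥ 0, c, d}  ½‖M p + B c + D d − z‖² + α·1ᵀp + ½γ‖c‖²

where `M` discretizes the Bateman response at 4 Hz (normalized to unit peak,
so driver entries read as SCR peak equivalents), `B` is a cubic B-spline
basis with 10 s knots, and `D` an affine offset/trend. Because `p ≥ 0` makes
the l1 term linear, the objective is smooth on the feasible set and is
solved by projected quasi-Newton iterations (L-BFGS-B) from a ridge tonic
start; additivity `z = tonic + phasic + residual` holds identically by
construction.

The l1 weight matters: under the unit-peak normalization, a weight much
below ~10⁻² makes a dense driver train cheaper than the spline at
representing slow drift, and the decomposition degenerates (the driver
absorbs the tonic). The default α = 0.05 (γ = 10⁻²) sits well past that
threshold: on simulated five-minute streams it recovers impulse times to
~0.14 samples, driver support with precision ≈ 0.98 / recall ≈ 1.00 at a
0.05 µS threshold, and the tonic with correlation ≈ 0.999, while responses
down to 0.05 µS remain detectable.

SCR peaks are local maxima of the phasic trace with trough-to-peak
amplitude; the registry's "peaks above 1 µS" count converts z-scale
amplitudes back to µS with the subject's SD, since a fixed µS threshold is
meaningless on a per-subject z scale. The EDA registry has 18 values per
paragraph: mean/SD/min/max for each of the z signal, the tonic, and the
driver (12), the same four statistics of peak amplitudes (0-filled when a
paragraph has no peak), and the two counts. Paragraph windows equal the
paragraph intervals exactly; a configurable post-offset latency pad exists
but is off by default.

## Detection

The modeling matrix holds one row per retained paragraph: 19 eye + 18 EDA +
4 behavioral features (reading duration, interest, difficulty, tiredness).
Participants who never reported mind wandering are excluded entirely — a
leave-one-participant-out fold for them would have no positive class.

Evaluation is nested leave-one-participant-out cross-validation. Inside
each outer training set: standardize with training statistics (constant
features dropped), oversample the minority class 1:1 with SMOTE (k = 5;
synthetic points are interpolations between minority neighbors and are
tagged so leakage checks can see them), and select hyperparameters by
stratified 3-fold inner cross-validation on weighted F1, with SMOTE applied
inside inner training splits only. Logistic regression is the untuned
baseline; random forest and RBF-SVM are tuned. The default forest grid is
deliberately compact — {100, 300} trees × depth {5, 10}, three combinations
spanning both axes — so a full nested evaluation of a 20-participant study
runs in about two minutes on one CPU; the grid is a plain list in
`ModelSpec` and can be widened freely. Reported metrics per fold: accuracy,
Cohen's kappa, AUC from predicted probabilities, and support-weighted
F1/precision/recall; aggregates are means and SDs over folds.

Feature attribution is a Monte-Carlo permutation-sampling Shapley estimate
on the positive-class probability, model-agnostic so the same contract holds
for all three families. Permutations are drawn in antithetic pairs (a
permutation and its reversal share one background row), which enforces exact
additivity per pair and makes the two-feature case exact.

## Behavioral statistics

Per-paragraph variables are aggregated to per-participant condition-cell
means and analyzed with a two-factor within-subject ANOVA. The
Greenhouse-Geisser epsilon of each effect is `tr(M)² / (q·tr(M²))` for `M`
the covariance of the effect's orthonormal contrast variables (Kronecker
contrasts for the interaction), clipped to `[1/q, 1]`, and scales both
degrees of freedom of the corrected p-value; the implementation reproduces
R's `car::Anova` epsilons and corrected p-values to seven digits. Simple
effects use Helmert contrasts with the control level last — (1, −1, 0) and
(½, ½, −1) for three levels — tested as one-sample t tests on per-subject
contrast scores. Binary thought-type indicators enter as
arcsine-square-root transformed per-cell proportions (an unasked indicator,
gated by attentional focus ≥ +3, counts as 0). The correlation screen
reports Pearson pairs with |r| ≥ 0.2 and p below threshold. Type-I
calibration of the corrected test uses 5,000 null panels of 30 subjects —
with much smaller panels the epsilon estimate's noise makes the corrected
test visibly conservative (rejection ≈ 0.038 at 20 subjects), which is a
property of the correction, not of this implementation.

## Synthetic data generator

The generator produces what the pipelines consume, with every latent
quantity retained as ground truth.

*Gaze*: a line-wise scan path over an 8-line page — log-normal fixation
durations (median 210 ms, σ_log 0.3), ~105 px word advances, 12% regressions
of 1–3 words, line-return sweeps — sampled at 90 Hz with 2 px within-fixation
jitter, 5 px transit noise, ~2% invalid samples, and pupil = participant
baseline + slow sinusoidal drift + noise.

*EDA*: tonic = baseline (2–8 µS) + two slow sinusoids (300 s and 120 s
periods, 0.3 µS amplitude), phasic = Poisson impulse train (3/min,
log-normal peak amplitudes with median 0.4 µS) convolved with the Bateman
kernel, plus 0.02 µS measurement noise — the same model family the
decomposition assumes, so decomposition tests are exact recovery tests.

*Design and labels*: paragraphs last ~25 s (≈61 words at a deliberate
reading pace) separated by 8 s rating gaps; mind wandering is Bernoulli per
paragraph at base rate 0.158, modulated by condition multipliers whose
defaults reproduce the directional cell pattern of the original design
(highest under sad music with expertise-matched text and under happy music
with unfamiliar text); each MW paragraph gets exactly one button press
inside its episode.

*What makes detection hard*: an episode starts at a uniform fraction of the
first 60% of its paragraph and runs to the end, so paragraph-level features
are diluted by a variable factor; per-participant traits (fixation-duration
baseline σ_log 0.18, pupil-noise ×e^N(0,0.25), SCR rate ×e^N(0,0.2), SCR
amplitude ×e^N(0,0.3)) shift the feature distributions of a held-out reader
relative to every training reader; and a per-paragraph attentional-state
multiplier (σ_log 0.22 on the fixation cycle, 0.45 on pupil variability)
adds MW-independent variation exactly where the MW effects live. Within the
episode the effect multipliers are exact: fixation duration ×1.4, fixation
count ×0.7 (achieved by rescaling the saccade cycle so both hold
simultaneously in expectation), pupil variability ×1.5, SCR rate ×2.5.
These spreads were calibrated once so that a tuned random forest on eye+EDA
features lands clearly above chance without being trivial (weighted
F1 ≈ 0.85–0.9, EDA-only ≈ 0.78 with kappa ≈ 0.15–0.2), and then frozen.

*What the generator does not emulate*: real text layout and word-frequency
effects on fixations, smooth pursuit and vergence, blink dynamics (invalid
samples are i.i.d., not blink-shaped), motion artifacts and electrode drift
in EDA, non-stationary reporting thresholds in the self-caught method, and
any content-level coupling between text semantics and thought content.
Passing tests therefore demonstrate that the pipeline recovers the signals
this model family generates — not that the original study's effect sizes
are reproducible from real recordings.

## Numerical choices and edge cases

- Population (ddof = 0) standard deviations throughout standardization;
  sample SDs in across-participant summaries.
- I-DT duration is `t_last − t_first` of the window; streams shorter than
  two samples yield no fixations; a paragraph whose training fold lacks a
  class is skipped with a warning rather than imputed.
- The decomposition accepts an iteration-capped solution only if the
  gradient tolerance was met; zero-variance pupil or conductance raises
  with the participant named.
- Feature tables are written with 17 significant digits and read back with
  exact-rounding parsing, so disk round-trips are bitwise lossless.
- Problem sizes in the reproduction suite — 1,000 oracle streams, 20
  five-minute decomposition streams, three full 20-participant studies,
  5,000 calibration panels — were chosen as the package's own benchmark
  conditions; each completes on a single CPU core in minutes.

## Known limitations

- The 19-feature eye registry resolves an ambiguity in its source
  convention (six bolded measures would imply 21 statistics); membership is
  configurable but the default follows the printed count of 19.
- Whether the 1 µS peak threshold should apply before or after
  z-standardization is unstated in the source convention; this package
  evaluates it on the raw µS scale.
- The driver's per-paragraph minimum is structurally zero (a sparse driver
  vanishes somewhere in every 25 s window), so `driver_min` is constant and
  is dropped by the fold scaler with a warning; it is kept in the registry
  because the registry is defined as the four statistics of each component.
- SMOTE interpolates in the standardized feature space; count-valued
  features (peak counts, fixation counts) become fractional in synthetic
  rows, which tree models tolerate but which has no physical reading.
- The detector is paragraph-level and offline; moment-to-moment detection
  is out of scope (the 4 Hz EDA rate and ~3 s SCR latency make it
  ill-posed at this sensor set).
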