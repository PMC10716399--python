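# Methods

## Design emulated by the synthetic cohort

Two groups (TV / NOTV) of `n_per_group` subjects, randomized 1:1 within
consecutive index pairs. Five training days with two daily sessions of
twelve 3-min typing lessons; the marker lesson L3 occurs four times per
session on day 1 and once per session on days 2–5. Pre and post the
training week each subject completes a TVA whole-report session (six
exposures from 10 to 200 ms, masked and unmasked, 16 trials per condition =
192 trials), a partial-report session (seven layout conditions — single
target, target with contralateral or ipsilateral distractor, bilateral
targets, mirrored over hemifields — 28 trials each), a GOT descending
series (3.5 → 0.5 mm, ten trials per spacing, stopping when accuracy drops
below 8/10), an MDT method-of-limits series (two determinations of ten
stimuli on the 0.25–8 mN factor-2 ladder), and a 10-min dictation.

## Generating models

**Typing.** Entered characters in a lesson are Poisson with mean

    baseline · learning_rate^(day−1) · group_gain^(day−1) [TV only]
             · di_uplift^(session−1) · subject_effect,

errors Binomial(entered, error_rate), correct = entered − errors. The
multiplicative form keeps counts positive and gives closed-form score
expectations: E[Gain_L3(X)] = (learning_rate·group_gain)^(X−1),
E[DI] = di_uplift, so every calibration below is analytic. Subject
heterogeneity is lognormal on the baseline (scale `subject_sd = 0.15`,
cancels exactly in all ratio scores) and on the learning rate (scale
`learning_rate_sd = 0.0729`, the component that creates between-subject
score variance). With `count_noise` off the generator returns the rounded
noiseless curve with zero errors (used by degenerate-curve tests).

Defaults: `baseline_correct_rate = 180` entered characters per 3-min lesson
(≈60 correct characters/min, a plausible novice touch-typing rate),
`learning_rate = 1.12`, `di_uplift = 1.05`, `error_rate = 0.06`. The group
effect `group_gain_multiplier = 1.06783` is the closed-form solution (see
`group_gain_multiplier_for_mle_diff`) making the true MLE group difference
0.103, and `learning_rate_sd` is set so the between-subject MLE standard
deviation is ≈0.103, i.e. a standardized group effect of d ≈ 1 — the
trial's reported headline contrast. These are the default study conditions,
not tuned quantities; both are overridable.

**TVA.** Trial outcomes are drawn by simulating the exponential race
itself: per-element finishing times `T_i ~ Exp(v_i)`, per-trial capacity
drawn from the fractional-K integer mixture (⌊K⌋ with weight ⌈K⌉−K, ⌈K⌉
with weight K−⌊K⌋), an element encoded iff it finishes within the
effective exposure among the first k finishers. The simulator is therefore
also the Monte-Carlo oracle against which the analytic probabilities are
tested. Generating truth (per group × phase): baseline `t0 = 15 ms, C = 20
items/s, K = 3.2, μ = 100 ms, α = 0.5, w_lat = 0.5`; post-test C rises by
14.89 (TV) / 14.35 (NOTV) items/s and K by 0.302 (TV) / 0.048 (NOTV), so
the between-group K_change difference is 0.254. The baseline C and K are
free choices (only the changes are pinned to the trial's reported
contrasts). The pre-test individualization of the partial-report exposure
is emulated as a single per-subject scalar: the exposure solving a 70%
single-target report rate at the subject's true parameters, clamped to
[10, 200] ms; the true adaptive staircase is not modelled.

**Sensory.** GOT accuracy is `0.5 + 0.5·logistic(slope·(ln g − ln g75))`
(chance 0.5 for the two-alternative orientation judgement; default
threshold 1.2 mm, slope 8 per log-mm). MDT detection probability is
`logistic(slope·(ln f − ln thr))` (default 0.8 mN, slope 6 per log-mN)
driving the alternating staircase. Defaults are identical pre/post and
across groups, mirroring the trial's null sensory findings.

**Randomness.** One root seed; every subject consumes substreams keyed
`(seed, stream-id, subject-index)`, so identical configuration and seed
give byte-identical datasets and enlarging the cohort leaves existing
subjects' data untouched.

## TVA model and fitting

Whole report with equal weights: each of n items finishes by τ
independently with `q = 1 − exp(−(C/n)·τ/1000)`; the score is the finisher
count truncated at capacity, mixed over the fractional-K pair — the
closed-form min(Binomial, k) law. Unmasked displays extend τ by a fitted
constant μ (iconic persistence). Partial report: element weights
`w_side · (1 or α)` with side weights (w_lat, 1−w_lat), rates `v_i =
C·w_i/Σw`; a target is reported iff it finishes within τ with fewer than
k competitors ahead, P = ∫₀^τ v_t e^(−v_t s) P(#others < k) ds with the
Poisson-binomial count over the other elements. The exact distribution of
the reported-target count (used by the likelihood) enumerates candidate
encoded sets; sets at full capacity require the k-th finishing time within
τ, integrated over the maximum finishing time of the set. All integrals use
a fixed 64-point Gauss–Legendre rule, which agrees with the Monte-Carlo
oracle to ~1e-4 on the test grid.

Fitting is deterministic: a coarse fixed grid over the bounded box (t0 ∈
[0, 60] ms, C ∈ (0, 200] items/s, K ∈ (0, n], μ ∈ [0, 500] ms) followed by
Nelder-Mead refinement from the best grid point; no stochastic restarts, so
fits reproduce without seeds. The t0 bound is a fixed 60 ms rather than the
smallest exposure: a threshold above the smallest exposure simply predicts
all-zero reports in that condition and remains identified by the
intermediate exposures, and clamping at 10 ms was found (by simulation) to
bias the fitted effective exposure and, downstream, α. Estimates at a box
boundary are flagged non-converged and the pipeline excludes them from
change scores with a reason code. Partial-report fitting holds (t0, C, K,
μ) fixed at the whole-report estimates — separable, mirroring the session
order — and maximizes over (α, w_lat) only; it requires at least one
distractor condition (else α is structurally non-identifiable) and targets
on both sides (else w_lat is). t0 is fitted but excluded from group change
analysis, which uses C and K only. Observed finite-sample behaviour at the
default 192 whole-report trials: C is estimated with a right-skewed error
(median ≈ +10%, within the recovery tolerance); error in the
whole-report stage propagates into α, so α should be interpreted jointly
with the C fit.

## Score and threshold estimators

Gain_L3 pools all day-1 L3 occurrences with equal weight; DI sums correct
characters over all twelve lessons per session; MLE averages the ten
components, and with missing components averages the available ones
(divisor reduced) while flagging incompleteness — the analysis tolerates
per-day missingness. GOT's g75 interpolates linearly between the bracketing
pair adjacent to the termination point (the last spacing at ≥75% accuracy
and the first below); accuracy at/above 8/10 counts as a pass (the
configurable reading of the "below 75% (8/10)" stop rule, whose two halves
are mutually inconsistent). Without a bracketing pair the estimate is
censored at the boundary of the tested ladder and flagged. MDT turning
points are the stimulus forces at detection↔non-detection reversals within
each determination; the threshold surrogate is their arithmetic mean (a
geometric-mean option exists, default off) with its standard error; series
without reversals are censored at the ladder boundary. Censored estimates
are excluded from relative pre/post changes with a reason code.

## Statistical decision rules

Parametric route iff Shapiro–Wilk p ≥ .05 in every group; Student vs Welch
by Levene (p ≥ .05 → pooled); otherwise Mann–Whitney U (mid-ranks, exact
method for small untied samples, normal approximation with continuity
correction otherwise). Paired comparisons gate on the difference scores
(paired t vs Wilcoxon signed-rank). The mixed ANOVA (pingouin) applies
Greenhouse–Geisser correction to the within-subject degrees of freedom when
Mauchly's test rejects sphericity and reports partial η²; post-hoc
contrasts are Tukey HSD. Cohen's d uses the pooled SD signed as
(NOTV − TV)/s_p, so a TV advantage is negative. Descriptive intervals use
mean ± 1.96·SD/√n; intervals on mean differences use t quantiles. Media
consumption tertiles are left-closed bins [0, 15), [15, 30), [30, ∞) h/week
(15 h/week falls in "Average"). No multiplicity correction is applied
across behavioural endpoints; the output metadata states this.

## What the synthetic data do and do not show

The generator reproduces the design's structure (schedule, marker-lesson
cadence, pre/post sessions, censoring and exclusion mechanisms) and the
statistical calibration of the estimators under known truth: passing tests
demonstrate correctness of the formulas, the fitting machinery and the
decision rules, plus nominal type-I error and power at the programmed
effect sizes. They do not show anything about real typing behaviour
(fatigue, lesson-content difficulty steps, error autocorrelation), real
TVA data (letter confusability, attention lapses, adaptive exposure
titration), or real psychophysics (lapse/guess rates beyond the logistic
form). Problem sizes in the test suite — 200 replicate cohorts of 10 per
group for calibration, 100 cohorts of 36 per group for power, 50 fit
replicates, 10^5-draw oracle comparisons — were chosen as the smallest
sizes at which the binomial/Monte-Carlo error bands in the corresponding
tests are decisive.

## Known limitations

- Whole-report weights are equal across display positions; positional or
  hemifield asymmetries in whole report are not modelled.
- μ is a single fitted constant; iconic persistence is in reality
  stimulus- and subject-dependent.
- The partial-report likelihood conditions on point estimates from the
  whole report; no joint fit or uncertainty propagation (bootstrap CIs are
  an extension point, deliberately not implemented).
- The MDT "threshold" is the method-of-limits surrogate (mean turning
  point), resolved only to the factor-2 ladder spacing; it is not a fitted
  psychometric threshold.
- Degrees of freedom in group comparisons follow complete-case exclusion
  per endpoint; no imputation.
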