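# vismotor

Behavioural analysis pipeline for a two-group randomized trial asking
whether intense visual stimulation (prolonged television watching, group
**TV**) enhances visuomotor learning relative to a no-visual-media control
(**NOTV**). Subjects learn touch-typing over five days (two daily 45-min
sessions of twelve 3-min lessons) and are measured pre/post on visual
attention (TVA whole/partial report), tactile acuity (grating orientation
task, GOT) and mechanical detection threshold (MDT, von-Frey method of
limits). The package implements the bespoke learning scores, the TVA
encoding model and its maximum-likelihood fitting, the psychophysical
threshold estimators, the gated group statistics, and a synthetic cohort
generator so the full pipeline runs with no external data.

## The measures

**Typing learning scores.** A lesson's correct count is `entered − errors`.
With L3 the designated marker lesson (eight occurrences on day 1, two per
day thereafter):

- `Gain_L3(X) = mean correct in L3 on day X / mean correct in L3 on day 1`
  (between-day learning; `Gain_L3(1) = 1` by construction),
- `DI = session-2 total correct / session-1 total correct` over all twelve
  lessons of a day (within-day learning),
- `MLE = (Σ_X Gain_L3(X) + Σ_X DI(X)) / 10` (composite motor learning
  efficiency; *not* maximum-likelihood estimation),
- dictation baseline: correct characters per minute (`ccpm`) in a 10-min
  dictation.

**TVA parameters.** Briefly flashed letter arrays are modelled as an
exponential race into a capacity-limited visual short-term memory: each
element has rate `v_i = C·w_i/Σw`; it is encoded iff its exponential
finishing time falls within the effective exposure
`max(0, t − t0) (+ μ if unmasked)` and fewer than `K` items have already
won. Whole report (equal weights) yields `t0` (perceptual threshold, ms),
`C` (processing rate, items/s), `K` (VSTM capacity, items, fractional K as
a two-point integer mixture) and `μ` (iconic persistence, ms); partial
report adds top-down selectivity `α` (distractor/target weight ratio) and
spatial laterality `w_lat`. Pre/post change scores: `C_change = C_post −
C_pre`, `C_rc = C_post/C_pre`, same for `K`.

**Somatosensory thresholds.** GOT: `g75 = g_low + ((0.75 − p_low)/(p_high −
p_low))·(g_high − g_low)`, the groove spacing interpolated to 75% accuracy;
MDT: mean ± SE of staircase turning-point forces on the 0.25–8 mN ladder.

**Statistics.** Shapiro–Wilk-gated t / Mann–Whitney comparisons (Levene
choosing Student vs Welch), paired t / Wilcoxon within groups, a two-way
mixed ANOVA (group × day) with Mauchly's test, Greenhouse–Geisser
correction and Tukey post-hocs, and confounder checks (age correlation,
media-consumption tertiles, content groups, gender).

## Worked example

```bash
vismotor simulate --seed 42 --n-per-group 5 --out demo/
vismotor report --run demo/
```

The simulated cohort (10 subjects) is scored, fitted and tested; the
summary starts:

```
endpoint        test    statistic       df      p_value effect_size
mle_group       student_t       -1.538  8       0.1625  -0.973
gain_l3_d2_group        student_t       -2.021  8       0.0779  -1.278
...
gain_l3_anova_within    mixed_anova_F   19.74   1.0694,8.55517  0.001391   0.7116
```

Reading it: the TV group's composite learning score is higher (Cohen's
d = −0.97 in the NOTV−TV convention, i.e. a TV advantage of roughly one
between-subject standard deviation — the generator's programmed effect),
but at 5 subjects per group the t-test is not significant (p = 0.16); the
strong within-subject day effect on Gain_L3 (F(1.07, 8.56) = 19.7 after
Greenhouse–Geisser correction) reflects the practice curve. Per-subject
outputs land in `demo/scores.csv` (e.g. subject S001, group TV:
`gain_l3_d5 = 3.03`, `mle = 1.48`), `demo/tva_fits.csv`,
`demo/tva_changes.csv` and `demo/sensory.csv`; every test's assumption log
is in `demo/stats_report.json`.

At the study's full size (36 per group) the programmed group difference in
MLE (0.103) is detected in ≥95% of replicate cohorts — see
`tests/test_acceptance.py`.

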