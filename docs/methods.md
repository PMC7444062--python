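# Methods

This note documents the models, rules, and design choices implemented
in `apa-task`: what each component computes, the parameters that matter
and their defaults, what the simulators do and do not emulate, and the
numerical decisions taken where the published task description leaves
the design open.

## Task structure and schedule generation

The default catalog holds 16 leisure activities — physical: ball
sports, biking, dancing, gymnastics/tumbling, outdoor play, running,
swimming, walking; sedentary: arts and crafts, board games, tablet,
listening to music, reading, talking, watching TV, video games — with
lower-snake tokens as stable file keys. Enumerating all unordered
pairs gives 120 trials: 64 cross-category, 28 within-sedentary, 28
within-physical; every activity appears in exactly 15 pairs.

How pairs are allocated to the four 30-trial blocks, and which side of
the screen each activity occupies, is not specified by the task
description, so both are package design choices:

* **Blocking** is a seeded random partition *stratified by pair type*
  (each default block gets 16 cross + 7 + 7 within-category pairs).
  Stratification keeps block composition comparable and prevents a
  block from containing no score-relevant (cross-category) trials.
* **Side placement** is randomized with a balance constraint: the
  sedentary member appears on the left in exactly half (±1) of the
  cross-category pairs, removing side bias from simulated data.
  Within-category pairs get fair-coin sides.

All randomization flows from a single integer seed; identical seeds
reproduce the schedule byte for byte.

## Scoring

**Explicit (VAS).** Liking and wanting ratings (0–100) are averaged
within category; every rated activity must belong to the catalog and
each category needs at least one rating.

**Trial cleaning.** Non-responses are always dropped. Reaction times
outside [0.2 s, 10 s] are dropped by default; both bounds are
configurable and a no-cleaning mode retains all responded trials.
Whether the original scoring trimmed outliers is unpublished; the
window is therefore explicit and optional, and N (the responded
cross-category trial count) shrinks accordingly.

**Implicit bias.** Only cross-category trials enter the score. The
reaction-time means (`RT_ALL`, `RT_SED`, `RT_PA`) are arithmetic means
over responded cross-category trials; a term whose win count is zero
contributes exactly zero and its empty RT mean is never evaluated. The
raw score `IW_SED − IW_PA` spans approximately [−2N, +2N], while the
published score spans −100…+100; we therefore rescale by `100/(2N)` —
the mildest transformation under which an always-one-category,
equal-RT respondent scores exactly ±100 — and clip reaction-time-driven
overshoot to the printed range with a `clipped` flag. The exact
normalization of the original scoring script is unpublished; this
choice is documented here and isolated in `compute_bias` should it need
revision. Two identities hold by construction and are asserted in
tests: `IW_PA = −IW_SED` exactly, and invariance of the score under a
common rescaling of all reaction times (only RT ratios matter).

## Respondent simulator

No generative model of choice or reaction time is published for this
task, so the simulator is the package's own: each activity carries a
latent utility; the latent sedentary preference θ is the mean sedentary
utility minus the mean physical utility. On each trial the left option
is chosen with probability `logistic(β·(u_left − u_right))` and the
reaction time is `rt_base · exp(−rt_slope·|Δu|)` times lognormal noise
— easy decisions are faster, so both win counts and RT ratios carry
information about θ, exercising every term of the bias formula. VAS
ratings are clipped affine maps of utility plus noise.

Defaults: per-activity utility scatter σᵤ = 0.3 around ±θ/2 (categories
recentred so realized θ is exact), choice sensitivity β = 4, rt_base =
1.5 s, rt_slope = 0.3 per utility unit, rt_sigma = 0.25, VAS map
50 + 30·u with rating SD 8, non-response probability 0. These are
chosen to give child-plausible reaction times (~1–2 s) and a strong but
imperfect mapping from θ to behavior; with them, the Spearman
correlation between θ and the computed bias over 200 simulated
respondents exceeds 0.9, and β = ∞ with zero RT noise reproduces the
±100 extremes exactly (utility ties fall to a fair coin).

## Cohort simulator

The cohort generator draws one row per child with the bias score and
the validation measures at configurable target correlations, using a
single-factor Gaussian model: the standardized bias score is the latent
factor, and each measure loads on it with its target correlation
(`X = μ + σ·(r·B + √(1−r²)·ε)`), making every marginal exactly normal
with the stated mean/SD and the implied correlation matrix (rank-1 plus
diagonal) positive semidefinite by construction. A full correlation
matrix may be supplied instead, with an explicit eigenvalue check.

Default marginals and loadings are the validation study's conditions:
bias 18.8 (46.2); retest bias with test-retest correlation 0.59;
free-play %sedentary 57 (36), r = 0.38; daily sedentary 151 (49) min,
r = 0; daily MVPA 45 (17) min with a sex-specific loading (−0.41 for
girls, 0 for boys); VO2peak 40.5 (8.1) mL/kg FFM/min, r = −0.52; BMI
z-score 0.69 (1.24), r = 0.35; %body fat 31.5 (9.0), r = 0.43; fat mass
index r = 0.44 with an assumed marginal of 7.0 (3.5) kg/m² (no
published marginal exists for FMI; the value is consistent with the
%body-fat marginal at typical pediatric BMI). Measurement-inclusion
missingness is emulated by randomly masking VO2peak in 30/60 and
accelerometry in 52/60 of children. Covariates: 50/50 sex split, ages
uniform on 8–17, white fraction 25/60.

What the generator does **not** emulate: non-normal margins (the real
bias distribution is bounded and was visibly skewed), shared method
variance among the adiposity measures beyond their common factor,
sex-specific marginal means, age trends, or any within-task structure
(cohort rows are scores, not trial logs). Passing recovery tests
therefore demonstrates that the pipeline's statistics are correct on
data with known ground truth — not that the study's effect sizes would
replicate.

## Measurement rules

* **Epoch classification** uses the pediatric cut-points on 15-s counts
  (CPE): 0–25 sedentary, 26–573 light, 574–1002 moderate, ≥1003
  vigorous, all bounds inclusive; the classifier partitions the
  non-negative integers.
* **Daily summaries** count awake-wear epochs only (sleep and non-wear
  excluded whatever their counts) at 0.25 min per epoch; intensity
  minutes sum to awake-wear minutes by construction. Percent-time
  metrics are per awake-wear time, not per 24 h. Wear/sleep annotation
  arrives as an input column; non-wear detection is a separate
  published algorithm and out of scope.
* **Wear validity** requires ≥4 days with ≥10 h awake wear including ≥1
  weekend day (all thresholds configurable).
* **Free play**: percent of coded 15-s intervals spent sedentary, where
  sedentary means not standing or moving; a three-level code set
  {SEDENTARY, STANDING, MOVING} is used, but only the sedentary /
  non-sedentary distinction feeds the metric. Inter-rater agreement is
  the percent of intervals coded identically.
* **VO2peak** is attained when ≥2 of four criteria hold: VO2 plateau
  (change < 2.1 mL/kg/min across the final workload increment — the
  stage pair chosen because a plateau is a test-end phenomenon; the
  source protocol does not say which increment), RER ≥ 1.0, HR ≥ 90%
  of predicted maximum (default model 208 − 0.7·age, configurable),
  RPE ≥ 19. A missing channel disables only its criterion. VO2peak is
  re-expressed per kg fat-free mass, which requires body weight to
  convert the weight-relative input.
* **Body composition**: %BF = 100·fat/weight, FMI = fat/height²; the
  identity FMI = %BF·BMI/100 is used as a test oracle.
* **Weight status**: overweight at BMI percentile ≥85 and <95, obesity
  at ≥95, severe obesity at BMI ≥ 120% of the 95th-percentile BMI
  (supplied by a pluggable growth-reference provider; with it missing,
  obesity is reported with a severe-undetermined flag). The
  underweight cut-off is not specified by the protocol; default
  percentile < 5, configurable.

## Questionnaires

The PSDQ-S (40 items, 1–6, 11 subscales) and BES (23 items, 1–5, 3
subscales) ship as skeletons: their subscale memberships and reversal
keys are the instruments' copyrighted scoring keys and must be supplied
from the source publications (`with_item_map`), rather than guessed.
The MFQ short form (13 items, 0–2, summed total 0–26) is complete.
Reversed items are recoded `min + max − response`. Missing data: a
subscale is scored when ≥80% of its items are present (configurable);
mean subscales use the present items, summed subscales are prorated by
`n_items/n_present`. With no missing items, prorated and plain scores
coincide.

## Statistics

Pearson correlations use pairwise deletion and a t-based two-sided p on
n−2 df. Partial correlations residualize both variables on the
covariate design (with intercept) by least squares on complete cases;
p uses n−2−k df; a rank-deficient design is rejected naming the
collinear columns. Covariate encoding: sex girl=1/boy=0 and a binary
white vs racial/ethnic-minority race indicator by default (full dummy
coding available). The test-retest coefficient is the single-measure
absolute-agreement ICC from the two-way mean squares,

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)),

with listwise deletion and the McGraw–Wong F-based 95% CI; with two
sessions the single-measure form is the one consistent with the
published reliability, and it is the primary implementation here.
Group comparisons use the pooled-variance independent t-test. No
multiple-testing correction is applied anywhere, matching the
validation analysis. The report generator runs the full grid and
records per-cell errors (zero variance, insufficient n) without
aborting.

## Problem sizes and tolerances

The recovery checks average over 1,000 simulated cohorts of n = 60
(the validation study's size); at that replicate count the Monte-Carlo
standard error of the mean ICC is ≈0.003 and of the mean Pearson r
≈0.004, well inside the ±0.03/±0.05 bands the tests assert. Formula
fidelity is checked on 10,000 randomized summaries against an
independently coded transliteration of the printed formulas at 1e-12;
the statistics functions are checked against brute-force
reimplementations at 1e-10 and cross-checked against `pingouin`.
Parameter recovery uses 200 respondents × 120 trials. The whole suite
runs in well under a minute on one CPU.

## Known limitations

* The bias-score normalization (`100/(2N)`) and the RT outlier window
  reproduce the published score range but are not the original
  (unpublished) scoring script; both are isolated and configurable.
* The cohort generator's Gaussian copula is a modeling convenience;
  pairwise correlations are the only published joint information.
* Skeleton questionnaire definitions cannot score until configured
  with the instruments' keys — by design.
* BMI percentiles and the 95th-percentile BMI are inputs; no growth
  reference ships with the package.
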