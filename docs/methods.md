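# Methods

This note documents the models and procedures implemented in `phclinic`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real checkup data.

## The stratification rule system

Each checkup item maps to one of four ordered grades,
GREEN < YELLOW < ORANGE < RED, through a threshold table. Numeric bins
are half-open intervals `[lo, hi)`: a printed threshold of the form
"≥ a" always places the value *a* itself in the higher-risk bin
(systolic 130 mmHg is yellow, 140 orange, 180 red; fasting glucose
100 mg/dl yellow, 126 orange, 200 red; SpO₂ 96 % green, below 90 % red).
The packaged default table (`src/phclinic/data/bangladesh_logic.yaml`)
encodes the full panel; loading any table validates that each item's
bins partition the measurement axis with no gap or overlap and that
every item has a GREEN bin. Not every item spans all four grades: waist,
waist/hip ratio and smoking stop at yellow; pulse and temperature stop
at orange. A smoker can therefore never be graded orange on smoking
alone — the table is applied literally, with no extrapolation.

Item-specific conventions:

- **Blood pressure** is one item with systolic and diastolic component
  bins; its grade is the worse of the two component grades, consistent
  with the worst-colour principle.
- **Blood sugar** uses fasting bins when the self-reported time since
  the last meal is at least `fasting_cutoff_hours` (default 8 h, the
  standard clinical fasting-glucose definition; the programme context
  never fixed a number, so it is configurable). An *unknown* meal time
  falls back to the postprandial bins — the standard conservative
  practice when fasting cannot be verified.
- **Waist** and **waist/hip ratio** are sex-specific (male ≥ 90 cm /
  ≥ 0.90; female ≥ 80 cm / ≥ 0.85 are yellow).
- **BMI** uses a supplied value when present, otherwise
  `weight / (height/100)²`; a supplied value disagreeing with
  height/weight by more than 0.5 kg/m² rejects the record.
- **Arrhythmia "yes"** and **urobilinogen "positive"** grade orange,
  following the column alignment of the printed table; the table leaves
  their yellow cells blank and a yellow reading would also be plausible,
  so both mappings are overridable in the rule-table file. Urobilinogen
  "negative" and "trace" are both green (trace urobilinogen is the
  physiologically normal finding).

The overall grade is `max` over all non-missing item grades
(worst colour), missing only when every item is missing. Items without
a measurement, or absent from the rule table, stay missing — never
defaulted to green. Only threshold-table items enter the aggregate;
free-text questionnaire content beyond smoking is not modelled.

## Synthetic cohort generator

The generator emulates the published *marginal* structure of the
screened population; one draw is one subject-visit row.

- **Strata**: (sex × area) sampled with weights 2844/16741 rural-male,
  4588/16741 rural-female, 6299/16741 urban-male, 3010/16741
  urban-female.
- **Age**: Normal(43.6, 14.0²) rural, Normal(29.6, 6.9²) urban, in
  years, truncated to [15, 90] by resampling and floored to integers.
- **Continuous measurements**:
  `value = mean + age_slope·(age − 35.8) + loading·z + sd·ε`, where `z`
  is a subject-level standard-normal latent risk factor shared by all
  items and ε is fresh visit noise. Out-of-range draws (physiologic
  bounds, e.g. SpO₂ ≤ 100) are resampled rather than clipped, keeping
  the distributions smooth. Systolic blood pressure uses loading 8 and
  residual SD 15, so its marginal SD is √(8² + 15²) = 17 around a mean
  of 121 mmHg, the published first-visit moments; its small default age
  slope (+0.2 mmHg/yr, centred at the cohort mean age) reflects the
  qualitative worsening of grades with age. **Follow-up visits** reuse
  the visit-1 subjects — same demographics and latent factors — and add
  the configured `followup_effect` (default −5 mmHg on SBP, the
  published decline from 121 to 116) plus independent visit noise.
- **Urinalysis** categories come from a probit link: category cutpoints
  are placed so the configured marginal probabilities hold while the
  latent factor shifts subjects toward the worse categories.
- **Booleans** (smoker, literacy, arrhythmia) are Bernoulli; smoker and
  literacy are subject-level (stable across visits).
- **Missingness** is independent per item; the only nonzero default is
  blood sugar at 1036/16741 ≈ 6.2 %, the published gap between the
  cohort size and the number of glucose tests performed.

Per-field child RNG streams (spawned seed sequences) make every field's
draws independent of the others, so shifting one measurement's mean
during calibration never perturbs another's sample path, and a fixed
seed yields byte-identical cohort CSVs.

The published record gives means and SDs only for age and SBP and
yellow-or-worse fractions for a few items; every other default
(heights, weights, glucose, pulse, urinalysis rates, smoking 22 %,
literacy 58 %) is a package choice of plausible adult values for the
setting, stated in `default_config` and not asserted as an estimate of
the unpublished data.

### Calibration

`calibrate_config` drives the fraction of subjects graded
yellow-or-worse on chosen items onto target values by 1-D bisection on
one location parameter per item (hip mean for the waist/hip ratio,
keeping waist in place; diastolic mean for blood pressure, keeping the
published systolic 121 pinned; the item's own mean elsewhere). The
fraction is evaluated on `n_calib` draws (default 50,000) at a fixed
seed, with missing grades counting toward the denominator — matching
how the published item fractions were quoted against the full cohort
size. Bisection stops within ±0.2 percentage points, comfortably inside
the ±0.5-point contract; a target that cannot be bracketed within ±16
marginal SDs of the knob (e.g. a blood-sugar fraction above the
measurement-completeness ceiling) raises a named error.

### What the generator does and does not show

The generator reproduces published *marginals* and a plausible
cross-item dependence through a single latent factor. It does not model
site-level heterogeneity, real glucose skewness (a truncated normal
under-weights the emergent orange/red glucose tail relative to a real
diabetic subpopulation), measurement error structure, or the joint
distribution of the unpublished raw data. Tests passing on synthetic
cohorts therefore validate the *pipeline machinery* — grading,
calibration, scoring, threshold economics — not any claim about the
original population beyond its printed summary statistics.

## Risk scoring

Labels are "blood-sugar grade is orange or red"; subjects without a
glucose measurement are excluded. Features are the non-glucose item
grades (numeric measurements binned at their own stratification
thresholds), 10-year age bands, and categorical demographics. A
blacklist (`blood_sugar_mg_dl`, `grade_blood_sugar`) plus the overall
grade (which aggregates the glucose item) are excluded and the
exclusion asserted, so the glucose result can never leak into its own
predictor.

The built-in reference scorer is an additive log-odds model: each
feature bin gets a weight-of-evidence
`log P(bin|pos) − log P(bin|neg)` with a Laplace pseudo-count
(default 1 per bin) so empty bins stay finite; a subject's score is
`logistic(prior log-odds + Σ weights + δ)`, where the offset δ is
solved once (Brent's method) so the mean training score equals the
label prevalence — naive-Bayes-style evidence summation over-counts
correlated features, and this one-parameter recalibration restores
calibration-in-the-large without touching the ranking. Missing or
unseen feature values contribute zero evidence, so a featureless record
scores at the (calibrated) prevalence.

The scorer exists to make the screening-economics demonstration
self-contained and transparent; the module's contract (`RiskScorer`:
deterministic feature-frame → scores in [0, 1]) accepts any external
classifier, and a 60/40 train/test split without replacement is
provided as the evaluation harness. On calibrated synthetic cohorts the
latent-factor signal yields held-out AUC ≈ 0.81–0.91 depending on seed;
no claim is made about AUC on the original data.

## Screening economics

The ROC is built with grouped tie handling (all records sharing a score
flip together; one operating point per distinct score, anchored at
(0, 0) for threshold +∞ and ending at (1, 1)); AUC is the trapezoid
rule. The implementation delegates the sweep to scikit-learn's curve
routine and is tested against an independent exhaustive-threshold
enumeration and a pair-counting AUC oracle.

Threshold selection:

- **Youden**: maximize J = TPR − FPR (the scaled distance from the 45°
  chance line). Since the balanced error rate is 1 − TPR + FPR = 1 − J,
  the same point minimizes BER; ties break toward the smaller FPR
  (fewer tests).
- **Budget**: sort scores descending, take the `max_tests`-th score as
  the threshold, flag everyone at or above it. If a tie group at the
  threshold would overflow the budget the entire group is excluded —
  deterministic and never over budget, preferred over testing an
  arbitrary subset of tied subjects.

Expected confusion counts round the *skipped* cells half-away-from-zero
— `tn = round(n_neg·(1 − fpr))`, `fn = round(n_pos·(1 − tpr))` — and
obtain `tp`, `fp` by differencing, conserving both class totals
exactly. At the published operating point (462/15,243, TPR 0.876,
FPR 0.059) this yields tn = 14,344 (from 14,343.66), fn = 57 (from
57.29), and 1304 tests performed out of 15,705, a cost fraction of
0.083. The published account of this example states the negative count
as both 15,246 and 15,243 in different places; the module takes class
counts as explicit inputs and makes no choice — the worked example uses
15,243, the value consistent with the printed products. Costs are free
parameters (`cost_per_test`; the contextual figures are US$0.60 per
glucose strip against a US$3-per-subject budget).

## Reporting

Percentages are computed in exact decimal arithmetic and rounded
half-up to two decimals, so every printed percentage reproduces from
its own counts (5419 of 16,741 → 32.37). Direct standardization
reweights stratum-specific prevalences by a reference (sex × age-band)
distribution, erroring on any positively-weighted reference cell with
no cohort subjects; age bands default to 10-year bins 15–24 … 75+
(configurable — the original banding was not stated). Paired
visit-to-visit change uses a plain paired t test,
`t = mean(d)/(SD(d)/√n)` with n − 1 df and a two-sided p — the
conventional choice for mean change; the original analysis reported
only a significance level without naming its test, and a rank test is
deliberately out of scope. Zero-variance differences are reported with
a `degenerate` flag instead of an undefined statistic.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the sizes the analyses
are stated for: calibration and prevalence checks at n = 50,000, the
full synthetic pipeline at n = 16,741 (the first-checkup cohort size),
paired follow-up at n = 2361 (the second-checkup cohort size), moment
and stratum checks at n = 100,000 with 4-standard-error bounds.
Bisection tolerances: 0.2 percentage points (calibration), 1e-10
(scorer offset). Grade ties in `youden_threshold` use a 1e-12 slack on
J before the FPR tie-break. All RNG flows from explicit seeds through
`numpy` seed sequences; no global RNG state is touched.

## Known limitations

- The generator's cross-item dependence is a single factor with
  hand-set loadings; real comorbidity structure is richer.
- The truncated-normal glucose model yields a thinner orange/red tail
  (≈ 0.5 % of subjects) than the original cohort's ≈ 2.9 %; the
  screening-economics arithmetic is unaffected (counts are inputs), but
  synthetic positive counts are smaller than real ones at equal n.
- Visit-2 marginal SDs are inherited from visit 1 (the published
  follow-up SBP SD of 15 vs 17 is not separately modelled; only the
  −5 mmHg mean shift is).
- The reference scorer is intentionally simple; it demonstrates the
  economics pipeline and is not a clinical risk model.
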