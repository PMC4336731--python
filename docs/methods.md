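# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `stentstrat`, in the spirit of a model-description
appendix. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model

One record is one coronary intervention. Consecutive interventions of the
same patient are treated as independent records; a `patient_id` column is
carried so grouped analyses remain possible, but nothing uses it by default.
Age, sex, diabetes and treatment are mandatory; everything else may be
missing. Endpoints are binary labels at fixed horizons: angiographic
restenosis at 6 months (≥50% diameter loss against the proximal reference on
quantitative angiography), clinical restenosis (target lesion
revascularization) at 1 and 3 years, and hazardous events (death, myocardial
infarction, stent thrombosis — explicitly excluding revascularization) at 1
and 3 years. A record not followed up has all endpoint labels missing.

The variable catalogue contains 30 clinical variables and 11 in vitro
diagnostic biomarkers, organised into overlapping feature sets C1/C2/C3
(29, 26 and 23 members by the catalogue's inclusion marks — the accompanying
prose in the source material says 28/25/22; the catalogue follows the marks
and we document rather than resolve the discrepancy) and B1/B2/B3 (8, 5 and
5 members). The packaged catalogue is a JSON resource and can be overridden
by a user file with the same layout.

Missing data are never imputed: every candidate classifier uses the
complete cases of its own (subgroup, feature pair, arm, endpoint) cell, and
cells with fewer than 100 rows or 10 positive labels are ineligible.

## Subgroups, trees, selection

Subgroups are conjunctions of {unconstrained, level} constraints on age
(≤60 inclusive / >60), sex and diabetes — 27 in total. Candidate trees are
all binary-split trees over those three variables with each variable used at
most once per root-to-leaf path (hence depth ≤ 4), deduplicated by the
partition their leaves induce: 146 distinct partitions, verified in the
tests against an independent brute-force enumeration of guillotine
partitions of the 2×2×2 constraint cube. (The source material reports "47"
candidate trees without stating a counting convention; no standard
convention we could construct — 16 level-uniform trees, 146 partitions, 244
ordered tree shapes — reproduces that number, so the enumerator's convention
is the partition count, stated explicitly and oracle-checked.)

Leaf classifiers are logistic regressions maximizing
`loglik − 0.01·‖β‖²` with the intercept unpenalized and no 1/n scaling, so
the effective regularization weakens with sample size exactly as the stated
penalty implies. The penalty is fixed rather than tuned: nested
cross-validation inside the already-exhaustive search would multiply cost by
the tuning-grid size for little benefit, and the fixed value is part of the
method's definition.

Feature-set and operating-point selection is exhaustive: for each test, all
eligible (clinical set, biomarker set) pairs (at most 16 including the
no-feature options; (NONE, NONE) is vacuous and always ineligible) × 19
specificity levels. Because the objective NPV(T_R)+PPV(T_H) is additive, the
search decomposes into two independent scans of 19·(number of candidates)
cells each — 38 evaluations with one candidate per test, 608 with all 16.
Metrics are computed by resubstitution on the training fold; the threshold at
a grid level is the smallest score value whose achieved training specificity
reaches that level. Ties are broken deterministically: higher metric, then
fewer encoded features, then lower set indices (no-feature first), then
lower specificity level. Candidates whose NPV/PPV denominator is zero are
excluded rather than scored zero, since the objective is undefined there.

Tree scoring sums leaf training confusion matrices element-wise and
recomputes NPV + PPV on the aggregate; trees with any ineligible leaf are
discarded (the single-leaf tree is always attempted, so training fails only
when even the whole population is ineligible). Ties break toward fewer
leaves, then enumeration order.

Prediction-sign convention: a *positive* prediction is score ≥ threshold.
The cascade suggests BMS when T_R is negative, DES when T_R is positive and
T_H negative, CABG otherwise. A record whose leaf models cannot score it
(era-masked features) is flagged and routed to the workflow default, DES.

## Effectiveness and costs

Treatment probabilities come from the closed forms in the README, with
prevalences, sensitivities and specificities taken from the evaluation
population's treatment arms. Conditionals mix two provenances:
classifier-based ("hat") estimates 1−NPV(T_R) and 1−NPV(T_H), and counted
("tilde") estimates — the hazard rate among records the restenosis test
called negative, and the restenosis rate among records suggested DES (i.e.
conditioning on both tests, the stricter of the two readings of the sDES
route; chosen because the suggestion, not the single test, defines the
route). CABG conditionals are literature constants (hazard 8.56%, restenosis
1.9%) supplied as configuration. Undefined conditionals (empty denominators)
are flagged and only raise if they would carry nonzero weight in a total.

The baseline workflow treats everyone with DES except the grey zone
ω = λ·P(3-vessel disease) with λ = 0.21, split half DES / half CABG; its
adverse-effect rates are counted directly from the evaluation DES arm.
Initial costs are (stent + one year of dual anti-platelet therapy) per
stented patient and C_CABG per surgical patient; corrective costs are
P(Hazard)·(½(C_MI + C_Stroke) + C_Corrective) + P(Restenosis)·C_Corrective.
Default stent costs are $11,866 (BMS) and $12,456 (DES) — the midpoints of
the ±25% sensitivity ranges $8,900–$14,833 and $9,342–$15,571, consistent
with the $590 BMS–DES gap — and $28,683 for CABG. The four remaining
constants (DAPT, MI, stroke, corrective procedure) have no defensible
published default here and are required configuration;
`placeholder_cost_table()` provides clearly labelled synthetic round numbers
for testing, under which the savings sign should not be interpreted. The
sensitivity grid varies both stent costs ±25% in 1.25% steps (41×41); the
surface is affine in each axis at fixed effectiveness.

## Cross-validation

`repeated_cv` draws a fresh k-fold split per repetition, stratified jointly
by treatment arm and the two endpoint labels so that small subgroups keep
both classes in every fold (the fold-assignment scheme is our choice; simple
random folds frequently produce single-class leaf cells at registry scale).
All selection happens on training folds; held-out per-record predictions are
pooled across folds within a repetition (micro-pooling) before any
performance or effectiveness quantity is computed — per-fold macro-averaging
would leave many fold-level NPV/PPV denominators empty in small subgroups.
Defaults: k = 10; 300 repetitions for confidence-interval-quality runs,
10 as the test-scale default. Intervals are empirical 2.5/97.5 percentiles
with numpy's linear interpolation.

## Synthetic cohort generator

The generator emulates the statistical shape of a two-registry PCI cohort:
2,733 interventions, 34.2% DES, 913/2,733 lost to follow-up, ages truncated
normal (mean 65, sd 10, minimum 18), 25% female, 28% diabetic, 25% 3-vessel
disease, three recording eras with weights (0.4, 0.3, 0.3) in which exactly
the feature sets C_k and B_k are observed. Continuous features are Gaussian
with a within-family equicorrelation of 0.2 and realistic location/scale;
binary and categorical features are Bernoulli/multinomial. Outcomes follow
leaf-subgroup-specific logistic models on the latent (unmasked) features.
Per-arm intercepts are calibrated by bisection so realized prevalences hit
their targets: BMS/DES angiographic restenosis 0.25/0.06 (midpoints of the
clinically reported 20–30% and 4–8% ranges), clinical restenosis
0.18/0.04 at one year and 0.23/0.08 at three, hazardous events
0.045/0.05 and 0.095/0.105 (similar across arms, rising with horizon —
calibration choices, not published values). Three-year labels are coupled to
one-year labels through a shared uniform draw, so event sets are monotone in
the horizon; the same coupling makes counterfactual labels under the
unassigned arm consistent. The planted truth (coefficients, linear
predictors, counterfactual probabilities and labels) is returned separately
and is never read by the fitting pipeline.

The default heterogeneous truth flips coefficient signs across diabetes
strata and scales magnitudes across age (and mildly sex) strata, so a single
population-wide model is misspecified while leaf models are well specified;
a homogeneous variant removes the heterogeneity for contrast tests. Active
features are restricted to variables observed in every era so that planted
effects are identifiable in all recording regimes.

What the generator does *not* emulate — and hence what passing tests do not
establish about real registries: treatment assignment is random given
nothing (no confounding by indication), features are jointly Gaussian within
blocks rather than skewed/heavy-tailed lab values, missingness is purely
era-structural (no informative missingness), outcomes are exactly logistic
in the features, and there is no time-to-event structure (all endpoints are
binary at fixed horizons, which is also a stated limitation of the original
formulation).

The cohort's canonical in-memory container is a pandas DataFrame;
`generate_cohort` returns it directly (pass `as_records=True` for
`PatientRecord` objects — the two representations round-trip through the CSV
layer).

## Numerical choices

* Optimizer: damped Newton from a zero start with analytic gradient and
  Hessian; the ridge term keeps the Hessian positive definite, step-halving
  guarantees monotone objective decrease, and an L-BFGS-B fallback covers a
  singular solve. The fit errors if the final gradient max-norm exceeds
  1e-6. An independent cross-check against scikit-learn's ridge logistic
  (C = 1/(2λ)) is part of the test suite.
* Standardization: continuous columns are z-scored with training-fold
  parameters; zero-variance columns map to zero with a warning; binary
  columns pass through as 0/1; categoricals are one-hot encoded against the
  most frequent training level and left unscaled.
* AUC uses the midrank (ties count half) convention.
* Specificity thresholds: ceil-based counting of negatives strictly below
  the threshold; when no observed score reaches a level, the threshold just
  above the maximum score (specificity 1) is used.
* Determinism: every stochastic step (generation, fold assignment) flows
  from `numpy.random.default_rng(seed)`; training is deterministic given the
  data.

## Scale choices

Exhaustive search over 27 subgroups × 16 feature pairs × 2 tests makes a
full 10×300 cross-validation a cluster-scale job; the packaged defaults for
tests and the acceptance script use what a workstation run needs: cohorts of
1,600–20,000 records, 5–10 repetitions, and single train/test splits for the
subgroup-vs-global contrast. At the default 2,733-record scale with ~5%
hazard prevalence, the ≥100/≥10 eligibility floor leaves only coarse
partitions eligible on the DES arm — the same "some subgroups could not be
analyzed" regime the method anticipates — so demonstrations of subgroup
advantage use 20,000-record cohorts where split leaves clear the floor.

## Known limitations

* Resubstitution metrics drive Eq.-style selection; with a weak penalty
  (0.01) and small leaves, training NPV = 1 operating points are selected
  preferentially. This reproduces the intended mechanism (zero estimated
  restenosis among BMS-suggested patients) but also means training
  objectives are optimistic; honest performance comes only from the held-out
  evaluation path.
* The two-test independence assumption is exact in the generator but only an
  approximation in any real cohort.
* Cost conclusions are entirely hostage to the four unpublished cost
  constants; with the shipped placeholders the savings estimate on synthetic
  data is negative, which demonstrates the arithmetic, not the economics.
* No grouped cross-validation by patient despite repeat interventions
  (matching the independence assumption above); the `patient_id` column
  makes adding it straightforward.
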