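# Methods

This note documents the models, rules and numerical choices behind
`hfgap`, and what the synthetic experiments do and do not establish.

## Phenotyping rules

**Ambulatory stream.** A patient is DIAGNOSED_HF on any I50-prefixed
event (first such date recorded); otherwise POTENTIAL_HF requires at
least one trigger-ICD event (I21, I25, I42, I48) *and* at least one
trigger procedure (BNP/NT-proBNP, echocardiography, cardiac
catheterisation, ergospirometry, Chagas serology); otherwise NEITHER.
The conjunction is the strictest reading of the underlying flowchart —
the procedures are described as reinforcing the ICD criterion — and is
switchable to a disjunction (`trigger_logic="or"`). Trigger events need
not co-occur or fall on the same date; any time within the extraction
window counts, since the flowchart imposes no proximity constraint. All
matching operates on 3-character ICD-10 prefixes: subcodes (I500) match
their parent (I50), because the case definitions cite only 3-character
codes.

The classification year is the year of the earliest qualifying event:
the first I50 for diagnosed patients, and the first date at which *both*
trigger conditions have been met (the later of the two first
occurrences) for potential patients. A 3-year lookback precedes the
study window so classifications in the first study years are not biased
by left truncation.

**Mortality stream.** A certificate with I50 anywhere — underlying
cause, Part I lines A–D, or Part II — is an HF_DEATH. With no I50
anywhere, a mortality-set code (B57, I05–I08, I21–I25, I34–I39, I42–I44,
I48, I49, I51) found on the Part I lines or Part II marks a
POTENTIAL_HF_DEATH; the underlying cause is deliberately excluded from
this search, so a certificate whose *only* cardiac code is the
underlying cause is OTHER. Subclassification priority is fixed as
ischaemic (I21–I25) > valvular (I05–I08, I34–I39) > cardiomyopathy
(I42–I44, B57) > other cardiac (I48, I49, I51); ischaemic priority is
required for consistency with the observed dominance of
infarction/ischaemia among potential HF deaths. Assigning B57 (Chagas)
to the cardiomyopathy class and I48/I49/I51 to a residual cardiac class
is this package's decision; only three subclasses are named in the
source material.

The ambulatory and mortality analyses never link records at patient
level; a person can legitimately appear in both.

## Underestimation sensitivity analysis

For yearly counts D (diagnosed) and P (potential) and identification
proportion p,

    U(p) = p·P / (D + p·P).

U(0) = 0 (best case), U(1) = P/(D+P) (worst case), U is strictly
increasing in p and scale-invariant in (D, P). The algebraic form was
reconstructed from the four published worked values (12%, 35%, 41%, 63%
at the 2018 counts), all of which it reproduces exactly; this
reconstruction is the module's central assumption. Display rounding is
half-up to a whole percent, matching the published reporting. Because
"average" scenario values are ambiguous (per-year vs pooled), the grid
emits both per-year rows and a pooled ALL_YEARS row from summed counts;
the per-year 2018 values are the ones pinned by tests. U(p) is undefined
only when D = 0 and p·P = 0; the pipeline skips degenerate years with no
diagnosed records.

`validate_against_truth` closes the loop on synthetic data: the
empirical identification proportion p̂ (fraction of potential-labelled
records that are latently true HF) plugged into U must agree exactly
with brute-force counting of true-but-uncoded cases over the latent
table — this is asserted, not assumed.

## Synthetic claims generator

The generator emulates the structure of ambulatory billing extracts and
death certificates with a latent truth table, so planted parameters are
recoverable downstream. Per patient: latent `true_hf ~
Bernoulli(prevalence)` (default 0.05); onset uniform over the 2018–2022
study window; a true-HF patient is ever coded with probability
`coding_probability` (default 0.6, an intermediate identification
scenario), with the first I50 event delayed 0–24 months after onset so
washout logic is exercised on both sides of the boundary.

Comorbidities and procedures follow an *additive presence model*: a
baseline Bernoulli component with identical rates for everyone (events
dated uniformly over the whole extraction window) plus an elevation
component only among true HF, sized so the overall presence probability
among HF equals `expit(logit(base) + shift)` — the planted log odds
ratio is therefore directly checkable from a 2×2 table. Present features
emit `1 + Poisson(1.5)` billed events. The timing of elevation events is
configurable (`signal_timing`): before onset (default, a pre-diagnostic
trajectory), strictly before the washout boundary, or confined inside
the 12-month washout window — the latter two exist solely to probe the
leakage guards. Keeping the baseline component identically distributed
across groups is what makes the washout-confined setting a clean canary:
after washout, cases and controls differ only through the removed
elevation events.

Default rates (per-window presence probabilities): trigger ICDs I21
0.03, I25 0.08, I42 0.01, I48 0.04; hypertension I10 0.25, diabetes E11
0.12, lipoprotein disorders E78 0.15, chronic kidney disease N18 0.05;
procedures ECHO 0.10, ECG 0.25, ABPM 0.03, BNP/CHAGAS_SERO 0.02,
CATH/ERGO 0.01; HF log-odds shifts of 0.5–1.8 concentrated on the
cardiology-investigation features. Demographics approximate the
descriptive tables of the underlying study population (age ~ N(61, 14²)
years clipped to [18, 100], 52% male, height ~ N(1.66, 0.09²) m, weight
~ N(72, 14²) kg); missingness is completely at random per field (race
8%, height/weight 10%, age 1%, sex 0.5%), since downstream handling is
by exclusion and imputation, not by modelling the mechanism. Deaths
occur at an annual rate of 0.01 (×5 among true HF) over the study years;
every true-HF decedent is an HF death, certified with I50 unless masked:
with probability `hf_death_masking_probability` (default 0.3) the
certificate carries an ischaemic/cardiomyopathy code on Part I line A
(weights ≈ 98% ischaemic) and no I50 anywhere. Non-HF deaths draw
non-cardiac underlying causes, with an 8% chance of a cardiac
contributing code — realistic false positives for the mortality proxy.

What the generator does **not** emulate: regional or facility structure,
care-seeking behaviour, coding-practice drift, COVID-era disruption, or
informative missingness. Passing tests therefore demonstrate the
*machinery* (rules, leakage guards, estimators, metrics) on data of
known structure, not the real-data performance of the models.

## Cohort construction and leakage control

Eligibility requires complete age, sex, race, height and weight.
Plausibility: age outside [18, 110] years or BMI outside [12, 60] kg/m²
drops the patient (eligibility criteria); count features above the
training 99th percentile are set missing and median-imputed rather than
dropping the patient — record-level rather than patient-level removal,
switchable, since extreme counts reflect data-entry errors rather than
ineligible patients.

Washout: for cases, only events dated `≤ first_i50 − 365` days
(inclusive boundary, plain calendar-day arithmetic, no leap-year
special-casing) and within the feature years 2018–2021 contribute to
features; controls contribute their full 2018–2021 window. A case left
with zero surviving events is retained with all-zero counts and
flagged. A machine-checked assertion re-verifies both rules on the final
feature-event table. Because controls have no index date, their
observation windows are longer than cases'; an optional matched
pseudo-index (each control receives a washout date sampled from the
cases' first-I50 distribution) equalises the windows. It is off by
default — the source study describes no control index date — but it is
used in the leakage-canary experiments, where the window-length
asymmetry would otherwise masquerade as signal.

Features are untransformed counts of 3-character ICD prefixes, ICD-10
chapters (static letter/number-range table) and procedures, plus age,
sex, race and BMI. Preprocessing state (medians, modes, p99 caps,
one-hot categories, optional standardization) is fitted exclusively on
training partitions, serialized as JSON, and applying fold-A state never
reads fold-B statistics.

Cohort sizes default to the published design: a balanced development
cohort of 10 000 cases + 9 995 controls with an 80/20 stratified split,
two validation cohorts of 20 000 and 17 041 disjoint from development
and from each other, and a ~2%-prevalence evaluation set formed from all
8 541 controls of the final validation cohort plus 175 of its cases.
The low-prevalence set is by construction a subset of that validation
cohort, mirroring its published definition; disjointness holds among
development and the validation cohorts. Sampling uses one documented
seed per assembly.

## Risk model

The boosting learner runs behind a thin interface in the package's
hyperparameter vocabulary (depth, learning_rate, iterations,
l2_leaf_reg, border_count), delegated to XGBoost's histogram method
(depth→max_depth, iterations→n_estimators, l2_leaf_reg→reg_lambda,
border_count→max_bin). The published final configuration
(learning_rate 0.083, l2_leaf_reg 25, iterations 900, depth 8,
border_count 30) ships as a named preset for structural reproducibility,
not as a claim about results on new data. The baseline is L2-penalised
logistic regression with class-balanced weights on standardised
predictors; constant features are dropped with a warning.

Model selection uses stratified 5-fold cross-validation with
fold-internal preprocessing (the CV routine takes a preprocessor
*factory*, making it impossible to pass pre-fitted state) and no
rebalancing or resampling within folds. The two-stage search first
samples uniformly from the broad space (depth 1–10, learning_rate
0.01–1, iterations 100–1000, l2_leaf_reg 2–100, border_count 10–35),
then refines within the narrowed space (depth 5–10 integer,
learning_rate 0.01–0.5 log-uniform, iterations 500–1000 integer,
l2_leaf_reg 2–35 log-uniform, border_count 10–35 integer) by maximising
expected improvement under a Gaussian-process surrogate (Matérn-5/2
kernel on unit-scaled, log-transformed coordinates; 256 random
candidates per iteration), warm-started from the stage-1 evaluations
clipped into the narrowed space. The decision threshold for confusion
matrices defaults to 0.5 and is a flag.

## Evaluation metrics

All metrics are computed from their definitions. AUC uses the rank
(Mann–Whitney) form, identical to the trapezoidal ROC area and to
pairwise concordance with ties counted half; it is property-tested
against an O(n²) enumeration oracle. Rates with zero denominators are
reported as not-available, never zero. Brier is the mean squared
probability error. ECE/MCE use 10 equal-width bins by default (quantile
binning by flag; empty bins skipped; the scheme is recorded in every
report) — no binning scheme is canonical, so it is always reported.
Calibration slope/intercept come from a maximum-likelihood logistic fit
of outcomes on logit-transformed predictions, with scores clipped to
[10⁻⁶, 1−10⁻⁶] so degenerate scores stay finite; calibration-in-the-large
(intercept with slope fixed at 1, via an offset GLM) is reported as a
secondary field; a constant-logit design raises.

Hosmer–Lemeshow groups by score deciles (ties kept together), with the
grouped Pearson form Σ(O−E)²/(E(1−E/n)) and degenerate groups merged
into a neighbour. The reference distribution depends on the design: the
conventional df = groups − 2 applies to development data (the default,
and the value carried in reports), while for external validation — scores
produced without estimating anything on the evaluated labels, which is
exactly the simulation design "labels ~ Bernoulli(score)" — the correct
reference is χ²(groups) (`n_fitted_params=0`); using g − 2 there
inflates the type-I error to ≈0.115 for deciles regardless of the data.
Both conventions are exposed.

Learning curves fix one stratified holdout and vary the training
fraction. Feature attribution is permutation importance (mean AUC drop
over seeded shuffles of one raw column at a time); a SHAP explainer can
be attached externally to the fitted estimator, but the native, tested
method is permutation importance.

## Problem sizes and numerical choices in the test-suite experiments

Monte-Carlo recovery tests use n = 20 000 patients with 99% binomial
intervals; mortality-masking recovery uses ≈5 700 deaths (≈4 200 among
true HF) at masking 0.2/0.5/0.8; the leakage canary uses n = 20 000
patients (prevalence 0.3, coding probability 1.0), a 1 000 + 1 000
development cohort and a 3-standard-error band around AUC 0.5 under the
Hanley–McNeil null variance; Hosmer–Lemeshow type-I error uses 500
replicates at n = 10 000; slope/intercept recovery uses n = 50 000;
cohort-assembly checks use a 100 000-patient pool. These sizes keep each
experiment's Monte-Carlo error well inside its acceptance band while
running in seconds to a few minutes on a single core.

## Known limitations

The underestimation analysis is deterministic: no confidence intervals,
and p is an assumption, not an estimate. The potential-HF proxy
misclassifies in both directions in multimorbid patients; U(p) inherits
that. Flowchart topology details that are not recoverable from the
source text (number of sequential gates, demographic gates) are resolved
by the declared conjunction rule. Whether potential-HF status requires
absence of I50 over all available years or only the study window is
resolved as: absence over study window plus lookback. Synthetic results
do not transfer to real claims; the published model-performance figures
require the original microdata and are out of reach by design.
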