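# Methods

`dosepair` quantifies how co-medication associates with dosage
adjustment in inpatient prescribing: for every (index drug,
co-medication) pair it estimates the adjusted odds that the prescribed
average daily dose of the index drug is changed during concomitant
exposure, relative to monotherapy, and then characterises the
significant pairs clinically and pharmacologically. This note documents
the models, the defaults and their rationale, the synthetic cohort the
package is validated on, and known limitations.

## Prescribed average daily dose (ADD)

A dosing regimen prescribes components (dose `d_i`, frequency `f_i`)
within a repeating interval of `t` hours. The ADD is

    ADD = (1 / t_days) * sum_i d_i * f_i     [per day]

Missing fields are filled by a fixed default cascade, in this order,
with every applied default recorded for audit: dose from package
strength x prescribed volume; volume assumed 1; interval derived from a
stated frequency (interpreted as a daily pattern); daily interval
assumed when neither interval nor frequency is stated; frequency assumed
1. "As needed" (PN) and variable-dose (VAO) prescriptions receive a
categorical ADD; one-time prescriptions and prescriptions that remain
incomputable are excluded. The cascade order is a package choice — the
rules themselves do not fix their interaction order — and recording the
applied defaults makes the exclusions auditable.

Downstream equality of ADD values is decided after rounding to 6
significant digits, so floating-point noise in human-entered decimals
never registers as a dosage change. Sequences mixing mass units are
converted through a fixed g/mg/mcg table; sequences with unconvertible
units are excluded rather than risking a spurious "change" at a unit
switch.

## Treatment episodes

All times are minutes since the cohort epoch; intervals are half-open
`[start, end)`. Within an admission, a drug's active timeline is the
union of its prescriptions' validity intervals, with abutting intervals
chained and overlapping duplicates merged (logged). The timeline of each
index drug is partitioned into maximal sub-intervals over which the set
of other active drugs is constant: empty set = monotherapy episode
(the model's reference condition), otherwise one concomitant episode per
co-medication active there. Each episode carries the index drug's
time-ordered prescriptions whose validity intersects it; `N` is their
count and `y` the number of adjacent ADD changes. A consequence of this
attribution is that a transition is counted only when the co-exposure
set is identical on both sides of the prescription boundary, which is
exactly the exposure condition the model estimates.

Admissions are pre-processed by combining a patient's re-admission
within 24 hours of discharge into the preceding admission.

Discontinuation of an index drug during a concomitant episode is flagged
when the index drug's last validity end lies strictly inside the
co-medication's active interval; a simultaneous end is *not* a
discontinuation (cessation must happen during, not with, the
co-medication).

Cohort-level selection retains index drugs with a monotherapy episode in
at least 50 patients and pairs present in at least 50 patients, and
drops drugs that are one-time orders in more than 70% of their
prescriptions from the co-medication role only. All three thresholds
are configurable.

## The dosage-adjustment model

For one index drug, every episode contributes a binomial observation
with

    logit(p) = b0 + b_comed + b_age*age + b_sex*sex + b_hospital
               + b_diagnosis + b_year + g_patient

where the co-medication factor has monotherapy as its reference level
and `g` is a patient random effect. Age is standardised; hospital,
diagnosis chapter and calendar year enter as reference-coded dummies.

**Trial counts.** An episode with `N` prescriptions offers `N - 1`
opportunities for a lagged change, and `y` counts adjacent unequal ADD
pairs, so the default binomial trial count is `N - 1`
(`trials_mode="transitions"`); episodes with a single prescription then
carry no information and are dropped from the likelihood. The
alternative `trials_mode="prescriptions"` (trials = `N`) is retained as
a sensitivity switch; note that it shrinks the apparent change rate of
short episodes by `(N-1)/N`, which differentially attenuates short
concomitant episodes relative to long monotherapy episodes and biases
odds ratios towards (and past) the null — measured on null synthetic
cohorts, it manufactures spurious ORs of 0.4–0.8.

**Priors.** By default, fixed-effect coefficients get independent
normal(0, 1) priors (normal(0, 0.5) for sex) and the patient
random-effect scale gets a half-normal(0, 1) hyper-prior
(non-centred parameterisation, with the patient effects entering the
predictor centred to zero mean so the overall level is carried by the
intercept alone). A fully hierarchical mode (`hierarchical=True`) places
half-normal scale hyper-priors on every coefficient block; it is not the
default because singleton-coefficient scale hyper-priors open funnel
geometries that produce persistent Hamiltonian divergences precisely
when an effect is near zero — the common case — which would invalidate
the zero-divergence convergence gate on otherwise well-behaved data. In
the hierarchical mode the weakly informed admin-covariate blocks are
non-centred and the data-rich blocks centred.

**Sampling.** The posterior is sampled with the package's adaptive
Hamiltonian Monte Carlo sampler: multinomial no-U-turn trajectories
(max tree depth 10), dual-averaging step-size adaptation to a 0.85
target acceptance, and a diagonal mass matrix estimated from the middle
of warmup. Defaults are 4 chains of 2000 iterations with 1000 warmup.
Per draw the sampler records divergences (energy error > 1000) and tree
depth; split R-hat and bulk ESS are computed per coefficient (via
arviz). A fit is declared converged iff max R-hat <= 1.1 and there are
zero post-warmup divergences. Fixed seeds make fits bit-reproducible on
one machine. The likelihood/gradient kernel is a single-pass compiled
(numba) routine with a pure-numpy fallback.

**Summaries and decisions.** Per co-medication the reported OR is
`exp` of the posterior median coefficient. Intervals are 89%
highest-density intervals — the shortest contiguous interval containing
`ceil(0.89 n)` sorted draws — which are more stable than 95% intervals
at moderate effective sample sizes. The ROPE (region of practical
equivalence) is (-0.05, 0.05) on the log-odds scale (a null region
around zero is only meaningful on the coefficient scale; the OR-scale
interval is the exponentiated HDI): reject the null when the HDI is
entirely outside the ROPE, accept when entirely inside, undecided
otherwise. A *significant dosage-adjusted pair* is converged +
reject + OR > 1; pairs with OR < 1 outside the ROPE are reported but
not flagged. A draw-fraction ROPE variant (95% of draws inside) is
available but off by default. Co-medication indicators perfectly
collinear with the intercept or with another indicator are flagged
unidentifiable and excluded from the significant set.

**Down-sampling.** Index drugs with more than 500,000 concomitant
episodes are reduced by keeping the 300 most frequent co-medications and
then sampling episodes stratified on the joint profile of age bin
(Rice's rule, `k = ceil(2 n^(1/3)) + 1`), sex, calendar year, hospital,
admission diagnosis and co-medication. Per-stratum counts are the
floored proportional allocations plus remainder-proportional randomised
rounding, which is unbiased for every stratum marginal even when strata
outnumber the target. Co-medications left with fewer than 50 patients
are dropped.

## Clinical post-hoc analyses

Exposed admissions (first exposure per patient) are matched 1:1 to
controls on the same index drug with a different co-medication, by
greedy nearest-neighbour matching on a logistic propensity score over
age, sex, diagnosis chapter, weighted Charlson score and medication
burden. Greedy order is seeded-random; distance ties break on the lowest
admission id. On the matched cohort, all models adjust for the matching
covariates and p-values are Bonferroni-corrected within one family per
endpoint type (configurable; family sizes are logged):

* *Discontinuation*: logistic regression of index-drug discontinuation
  on exposure.
* *Mortality (30 d post-admission)* and *readmission (30 d
  post-discharge)*: Cox partial likelihood stratified by matched pair
  with Breslow ties. For two-subject strata this reduces exactly to
  conditional logistic regression on within-pair covariate differences
  (one term per informative pair; a tied double event contributes both
  mirrored terms), which is the default engine; a generic stratified
  fitter (lifelines) is available as `cox_engine="lifelines"` and the
  test suite checks the two agree. The conditional form is orders of
  magnitude faster at thousands of strata.
* *Length of stay*: stratified Poisson regression fitted through its
  exact conditional likelihood — within a 1:1 pair, Poisson counts
  conditioned on their total are binomial with logit equal to the
  exposure effect plus covariate differences — as a binomial GLM on pair
  sums. LOS is taken from the admission containing the exposure.
* *Enrichment*: logistic regressions of each diagnosis code and each
  abnormal blood test present in at least 50 matched patients; blood
  tests without a row for an admission are treated as within reference
  range (no test ordered implies no suspicion of altered physiology).

Inestimable endpoints (no events, no informative pairs, separation) are
reported with an `estimable=False` flag rather than a number.

## DDI / pharmacokinetic annotation and group comparison

Significant pairs are cross-referenced (unordered) against a binary DDI
table; shared pharmacokinetic activity means both drugs act — as
inducer, inhibitor or substrate; role identity is not required — on a
common protein from the regulatory-agency list of CYP enzymes and
transporters; a variant link means an annotated gene variant of one drug
maps to a protein that metabolises or transports the other. Literature
evidence is a co-mention count (absent pair = 0). Known-DDI and
unknown-DDI groups are compared on patient volume, co-mentions and OR
with the two-sided Mann-Whitney U test (exact when `n1*n2 <= 400` and
tie-free, otherwise normal approximation with continuity and tie
correction), overall and per therapeutic (ATC level-2) group when both
classes have at least 5 members. The effect size is `r = |z|/sqrt(n)`,
labelled with the conventional 0.1/0.3/0.5 cut-offs (the magnitude
labels have no other standard numeric definition). Non-normality
motivating the rank test can be checked with Shapiro-Wilk.

## Synthetic cohort

Real inpatient EHR data cannot be shipped, so the package carries a
generator whose defaults define its validation conditions. Patients
(default 1000; age ~ N(62, 18) clipped to 18–100, even sex split)
accrue 1–3 admissions over a 2008–2015 window with lognormal(1.5, 0.5)
whole-day stays. One designated index drug is present in 80% of
admissions for the full stay; a designated co-medication in 35% on a
day-aligned sub-window; remaining drugs appear as fillers (10% each).
Drug courses are daily prescriptions from a regimen menu whose entries
have distinct ADDs; at each successive prescription the regimen is
resampled (to a different entry, so the ADD provably changes) with
probability given by the same logistic model the inference stage fits —
baseline logit -1.5 (a ~18% per-day change rate), planted pair effects,
modest covariate effects (age 0.2, sex -0.1, hospital 0.1, diagnosis
0.15, year 0.05; categorical levels spaced linearly), and a patient
effect with SD 0.3. Because co-medication windows are aligned to the
index drug's daily grid, the exposure used when a change is drawn is
exactly the exposure the episode builder attributes to that transition —
forward simulation and inference agree by construction. PN/VAO courses
(5%), one-time orders (configurable per drug) and recoverably missing
dose fields (5%, strength-encoded) exercise the exclusion and default
rules without perturbing the change statistics.

Clinical outcome effects are planted for a designated pair:
multiplicative hazards on 30-day mortality (exponential, ~4% baseline)
and readmission gaps, a multiplicative LOS factor, extra discontinuation
log-odds (discontinuation truncates the index course strictly inside a
co-medication window, at a base rate for any co-medication so control
arms are never degenerate), and enrichment log-odds for a designated
blood test and diagnosis code. DDI, pharmacokinetic-role, variant and
co-mention reference tables are generated alongside. Identical seeds
reproduce every table byte-for-byte.

What the generator does *not* emulate: realistic ATC marginal
frequencies and code hierarchies, within-day dosing times, out-of-
hospital prescribing, correlated multi-drug regimen changes, or
informative censoring. Passing the validation suite therefore shows the
pipeline is correct under its stated generative model, not that the
clinical estimates transfer to any particular health system.

## Validation problem sizes

The parameter-recovery study uses 20 seeded cohorts of 5000 patients
(half receiving the index drug, 40% of those the co-medication, one
admission each) with a planted log(2) pair effect, fitted at reduced
MCMC settings (2 chains x 1000 iterations, 500 warmup); the 89% HDI
must cover the truth in at least 16 of 20 replicates and the median OR's
log-scale bias must stay below 0.15. Null calibration uses 20 cohorts of
1200 patients with a zero planted effect (ROPE reject rate <= 15%) and
200 directly simulated null matched cohorts of 80 pairs for post-hoc
type-I error (exact binomial compatibility with 5% at alpha = 0.01).
Episode construction is checked exactly against a per-minute active-set
enumeration on 100 random admissions, and the HDI against exhaustive
shortest-window search on 50 samples.

## Known limitations

* One regression per index drug treats that drug's co-medication effects
  jointly but ignores higher-order drug combinations.
* The patient random effect captures between-patient heterogeneity but
  not within-patient time trends; weight, kidney and liver function are
  not modelled.
* The conditional Cox engine is exact only for 1:1 matched strata (the
  only design the pipeline produces); use the lifelines engine for
  anything else.
* Wald p-values in the post-hoc models are asymptotic; with very few
  informative pairs an endpoint is flagged inestimable rather than
  reported.
* The generator's day-grid alignment slightly idealises prescription
  timing; arbitrary-interval layouts are covered by the per-minute
  oracle tests rather than the generator.
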