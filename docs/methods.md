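# Methods

## Study design implemented

The pipeline reproduces an incidence-density matched cohort design on
registry-style data.  Exposure is the first diagnosis of a common psychiatric
disorder (anxiety, depression, stress-related codes) from any source
(inpatient, primary care, self-report); outcomes are hospitalizations for
grouped cardiovascular diagnoses (3-digit ICD-10 groups from inpatient
records, primary + secondary diagnoses; a `primary_only` switch restricts to
primary diagnoses as a sensitivity definition).  Each exposed person's
diagnosis date is the index date; persons with any studied outcome strictly
before index are excluded (a same-day outcome is retained and becomes an
event half a day after index, keeping every interval's stop strictly after
its start).  Up to *m* = 5 comparators per index patient are sampled without
replacement from persons matched on sex, deprivation quartile and birth year
±2 who are alive, uncensored, exposure-free and outcome-free at the index
date.  Comparators may become exposed later (their comparator follow-up then ends at
their own first exposure diagnosis).  Cross-set reuse of comparators is the
standard incidence-density convention and the package default
(`reuse_across_sets=True`); setting it false makes matched sets disjoint,
which matters for inference — shared comparators correlate sets, and the
independent-strata Wald standard errors then understate sampling variance by
5–10% at realistic reuse levels (measured by simulation).  Calibration
checks of test size therefore use unique comparators; note that a matched
cohort whose baseline table counts exposed + 5×exposed *distinct* persons has
effectively used unique controls.

Follow-up runs from index to the earliest of outcome, death, loss, the
administrative end of follow-up (1997-01-01..2019-12-31 calendar window,
ending 2019-12-31), and, for comparators, own exposure.  Dates are whole
days; person-years are days/365.25; follow-up windows use months of
365.25/12 days.

## Estimation

Hazard ratios come from a Cox model stratified by matched-set identifier,
maximizing the stratified partial likelihood with Newton–Raphson on the
analytic gradient and observed information.  Rows are counting-process
intervals `(start, stop]`; the risk set of an event at `t` inside a stratum
is `{i : start_i < t <= stop_i}`, implemented with per-stratum suffix sums
over two sorted orders so each Newton iteration is O(n log n) once and O(n·p²)
thereafter.  Ties use the Breslow approximation by default; matched-set
strata essentially never contain tied events, and Efron is available as
`ties="efron"` (it matches lifelines on heavily tied data to 1e-5).
Convergence: max |score| < 1e-8 or relative log-likelihood change < 1e-10,
at most 100 iterations; covariates are mean-centered internally and steps are
halved when the likelihood would decrease.  Standard errors are the inverse
observed information; 95% CIs use Φ⁻¹(0.975) = 1.959964 (reports round to two
decimals).

Separation (monotone likelihood) is detected per coefficient: after
iteration stops, any coefficient beyond ±10 on the log scale is flagged as
diverged, the fit carries a warning, and downstream tables render the
affected contrast as not estimable rather than printing an enormous number.
A nuisance dummy with no events in its level may diverge without invalidating
the exposure contrast; only divergence of the contrast of interest makes a
row non-estimable.  Strata without events or without within-stratum covariate
variation contribute nothing; if no informative stratum exists the fit raises
`NoInformativeStrataError`.

Categorical covariates (education, ethnicity, smoking, BMI category) are
dummy-coded against fixed reference levels with an explicit "unknown" level
retained.  The adjustment cascade is: model1 — sex, birth year, deprivation,
ethnicity, education; model2 — + BMI, smoking, history of other psychiatric
disorders, comorbidity index; model3 — + family history of CVD.

Window-stratified estimates come from `split_followup`, which partitions
intervals at cutpoints with exactly conserved person-time (shared boundary
values telescope) and attaches the event flag to the sub-interval containing
the event time; per-window fits are separate stratified Cox models, not
time-varying coefficients: the early and late follow-up estimates are
separate models, which is the natural reading of a within-versus-beyond
six-months analysis.

Subgroup comparisons use the Wald z-test on two independent log-HRs with SEs
recovered from the printed CIs, `se = (ln hi − ln lo) / (2·1.959964)`; effect
modification is additionally tested with an exposure × modifier product term
in the stratified Cox model (modifier main effect included — it varies within
matched sets because sets are not matched on family history or polygenic
score).  Polygenic-score tertiles are computed among non-missing scores;
persons with missing scores are excluded from score-stratified fits.
Subgroup models keep the full adjustment set minus the stratifying variable.

Conditional logistic regression is the same engine applied to case–control
sets placed at one common time with the case as the event; for 1:1 sets with
a binary predictor the estimate equals the discordant-set ratio exactly
(asserted in tests to 1e-8).

## Trajectory algorithm

Step 1 screens grouped diseases by exposed-case count (strictly more than
`min_cases`, default 200) and fits one stratified Cox model per disease with
the full adjustment set; significant means HR > 1 and p < 0.05/k with k the
number of diseases tested (non-estimable diseases stay in k).  Step 2 forms
all ordered pairs of significant diseases, and for each unordered
co-occurrence among exposed persons counts which diagnosis came first
(same-day pairs are excluded from the informative n; the design is silent on
sidedness, so the test is one-sided exact binomial on the observed-majority
direction against P = 0.5).  The prevalence filter (`n_both >= min_co`,
default 100) is applied before the binomial tests and the Bonferroni
denominator is the number of pairs passing prevalence; the opposite order is
available via `prevalence_first=False`.  Step 3 confirms each surviving
directed pair by risk-set sampling within the exposed cohort: for each D2
case, up to 5 controls alive, uncensored and D2-free at the case's follow-up
time, matched on sex and birth year ±2, with the predictor "D1 strictly
before that time"; conditional logistic regression (unadjusted by default)
with Bonferroni denominator equal to the number of directed pairs tested in
this step.  Steps 2–3 run within the exposed cohort, since the target is the
progression structure downstream of the exposure.  The matching factors and
ratio of this nested design are package defaults, declared here rather than
inherited from an external protocol.

Network assembly takes the confirmed edges (OR > 1 and Bonferroni-significant
p); cycles are resolved by repeatedly removing, within a detected cycle, the
edge with the largest p (tie: smaller OR), logged and recorded on the graph.
Layers: nodes without incoming edges get layer 1, otherwise 1 + max
predecessor layer, so every retained edge points to a strictly later layer.

## Synthetic cohort generator

Each person carries competing exponential hazards, piecewise-constant in
their current state: psychiatric onset (default 0.008/person-year),
first occurrence of each disease group, death (0.005/py) and loss to
follow-up (0.002/py), all within the 1997–2019 calendar window.  The hazard
of disease *d* at time *t* is

```
baseline_d · exp( exposure_log_hr_d · 1[onset ≤ t]
                + Σ_i progression_log_or[i,d] · 1[disease_i ≤ t]
                + family-history, PRS and covariate terms
                + modification_log_hr_d · 1[onset ≤ t] · modifier )
```

Covariate marginals are chosen to resemble a mid-life volunteer cohort: sex
~ Bernoulli(0.65 female), birth year uniform 1937–1970, deprivation score
standard normal, family history prevalence 0.556, per-disease polygenic
scores standard normal with 27.19% missing, family-history and per-SD PRS
log-HRs log(1.3).  The effect-modification term multiplies the exposure
effect for modifier carriers (family history by default; per-disease PRS as
an option); zero is the null-modification scenario.  Psychiatric diagnoses
are labelled with mixed sources (10% inpatient-primary, 5%
inpatient-secondary, 60% primary care, 25% self-report); disease events are
hospitalizations and carry inpatient sources only (65% primary, 35%
secondary).  An early version labelled disease events with mixed sources
too; because outcome ascertainment reads inpatient records, roughly half the
events were invisible, persons whose first event had a GP/self-report label
stayed in risk sets with zero residual hazard, and recovered log-HRs were
attenuated by ~0.03 — the current source semantics removes that artefact and
matches how such registries are actually structured.

The generator emulates staggered exposure onset (exposure is one more
competing event, so the exposed fraction accrues over calendar time exactly
as incidence-density matching assumes), first-occurrence-only diagnoses, and
death/loss truncation.  It does **not** emulate diagnostic coding noise,
delayed presentation, covariate-dependent exposure onset (no confounding by
the simulated covariates unless effects are configured), or calendar trends;
passing recovery tests therefore demonstrates estimator correctness under
the design's assumptions, not robustness to real-world measurement error.

`planted_trajectory_config(chain, strength)` builds the progression-recovery
scenario: chain diseases at baseline 0.0018/py, exposure log-HR log(2),
`strength` on consecutive pairs, zero elsewhere.  These scaffolding values
were calibrated once, by pilot simulation, so that at n = 100,000 the
adjacent pairs co-occur in comfortably more than 100 exposed persons while
the transitive first→third pair stays below the prevalence filter — the
planted chain is then recoverable *exactly*.  They are test scaffolding, not
estimates of any published progression effect.

## Problem sizes used in checks

Estimator checks run at the scale a single workstation handles comfortably:
hazard-ratio recovery and CI coverage on cohorts of 50,000 (200 null
replicates for coverage, 100 for bias), interaction type-I error on cohorts
of 20,000 (500 replicates), and planted-chain trajectory recovery on cohorts
of 100,000 (50 replicates).  Estimator-calibration scenarios switch off the
simulator's unobserved heterogeneity (per-disease polygenic effects) so the
conditional null being tested is the generative null, and the type-I
scenario uses unique comparators so matched sets are independent as Wald
inference assumes; both conditions are the study design's own assumptions,
not conveniences.  The acceptance script uses the same scenarios with
somewhat fewer replicates.

## Known limitations

Death is treated as censoring, not a competing risk; proportional-hazards
diagnostics are out of scope; no mapping between coding dialects (code lists
must enumerate all codes per group); the conditional-logistic OR of step 3 is
a rate-ratio estimate under incidence-density sampling and shows mild
attenuation for very large planted effects (log-OR ≈ 2.2 recovered for a
generative 2.5); baseline covariates enter as fixed values measured at
baseline, so time-varying confounding is out of scope.
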