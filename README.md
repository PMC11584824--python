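# epitraj

Matched-cohort survival analysis and disease-trajectory networks for
registry-style diagnosis data.

`epitraj` is built for the epidemiological question: *after a first diagnosis
of a common psychiatric disorder (anxiety, depression, stress-related
disorders), how does the risk of cardiovascular disease (CVD) hospitalization
evolve, is it modified by pre-existing susceptibility (family history,
polygenic risk), and in what temporal order do the downstream cardiovascular
diagnoses arrive?*  The real cohorts that motivate this design live in
access-restricted biobanks, so the package ships a seeded multistate cohort
simulator that emulates the data structure end to end — every stage of the
pipeline is testable on a laptop, and planted generative effects can be
checked against what the estimators recover.

## What it implements

**Cohort construction.** From long-format participant and diagnosis-event
tables: exposure ascertainment (first qualifying diagnosis across inpatient,
primary-care and self-report sources), exclusion of persons with any studied
outcome before their index date, and incidence-density matching — for each
exposed person at their diagnosis date, up to *m* comparators matched on sex,
deprivation quartile and birth year (±2 years), drawn from persons still at
risk, outcome-free and exposure-free at that date.  A comparator may later
become exposed; their comparator follow-up is censored at their own first
exposure diagnosis.

**Stratified Cox estimation.** Hazard ratios come from a Cox model whose
partial likelihood is computed within matched sets, eliminating the set-
specific baseline hazard:

```
h_is(t) = h_0s(t) · exp(β·exposed_i + γ'z_i)
```

fitted by Newton–Raphson on the analytic score and observed information
(Breslow tie handling by default, Efron available), on counting-process
intervals `(start, stop]` so that follow-up can be partitioned into windows
(≤3, 3–6, 6–12, …, >240 months) with person-time conserved exactly.
Effect modification (family history yes/no; polygenic-score tertiles) is
assessed two complementary ways: Wald tests comparing
subgroup log-HRs, and product interaction terms in the Cox model.
Conditional logistic regression for matched case–control sets is fitted by
the same engine (all set members at a common time, the case as the event —
the two likelihoods coincide).

**Disease-trajectory networks.** A three-step algorithm run within the
exposed cohort: (1) per-disease stratified Cox screening — diseases with
more than `min_cases` exposed events and HR > 1 at a Bonferroni-corrected
level; (2) temporal directionality — for each co-occurring disease pair with
at least `min_co` carriers of both, an exact binomial test of whether one
diagnosis order dominates (same-day pairs are uninformative); (3) nested
case–control confirmation — for each D2 case, risk-set-sampled controls
matched on sex and birth year, conditional logistic odds of a prior D1
diagnosis.  Confirmed edges (OR > 1, Bonferroni) form a directed network;
cycles are resolved by deleting the weakest edge, and each node gets a layer
(1 + longest confirmed path from a source), read as "how early after the
exposure this disease is affected".  The network is exported as GraphML and
JSON.

## Worked example

`examples/config.yaml` simulates 20,000 persons over 1997–2019 with a
generative exposure hazard ratio of e^0.405 ≈ 1.5 on six disease groups and a
planted progression chain I10 → I21 → I50 (hypertension → myocardial
infarction → heart failure), then runs the whole pipeline:

```bash
epitraj all -c examples/config.yaml
```

Outputs land in `scratch/example_run/`.  Highlights from this exact run:

* `flow.json` — 3,229 exposed identified, 1,019 excluded for an outcome
  before index, 2,210 analysed; 5 × 2,210 = 11,050 matched comparators.
* `reports/hazard_ratios.tsv` — any-CVD, whole period, fully adjusted:
  989 exposed vs 3,696 comparator cases (49.5 vs 35.7 per 1000
  person-years), HR 1.36 (1.27–1.47); within six months of index the HR is
  higher, 1.42 (1.04–1.93), matching the generative early-excess pattern.
* `trajectory/run-manifest.json` — 5 diseases screened in, 4 significant,
  12 ordered pairs, 4 past the prevalence filter, 3 confirmed edges.
* `trajectory/trajectory_network.json` — layers I10 = 1, I21 = 2, I50 = 3:
  the planted chain, recovered with correct orientation (plus the transitive
  I10 → I50 edge, which the example's lowered co-occurrence threshold lets
  through).

The same stages are available individually (`epitraj simulate|match|cox|
modify|trajectory`), all driven by one YAML config and one seed; reruns with
the same config and seed are byte-identical.

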