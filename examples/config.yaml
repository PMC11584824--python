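# Example end-to-end run on a simulated cohort.
# `epitraj all -c examples/config.yaml`
codelist: examples/codelists.yaml
outdir: scratch/example_run
seed: 42
matching_ratio: 5
followup_cutpoints_months: [3, 6, 12, 18, 24, 60, 120, 240]
primary_only: false
simulate:
  n_individuals: 20000
  psych_onset_rate: 0.008
  diseases: {I10: 0.015, I20: 0.004, I21: 0.003, I48: 0.004, I50: 0.002, I63: 0.002}
  exposure_log_hr: {I10: 0.405, I20: 0.405, I21: 0.405, I48: 0.405, I50: 0.405, I63: 0.405}
  # planted progression: hypertension -> myocardial infarction -> heart failure
  progression_log_or_matrix:
    - [0.0, 0.0, 2.0, 0.0, 0.0, 0.0]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    - [0.0, 0.0, 0.0, 0.0, 2.0, 0.0]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
trajectory:
  min_cases: 100   # scaled for the 20k example cohort (200 at full scale)
  min_co: 50       # scaled for the 20k example cohort (100 at full scale)
  alpha: 0.05
  m_controls: 5
  prevalence_first: true
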