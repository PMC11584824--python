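# Code lists mapping 3-digit ICD-10 codes to exposure and outcome groups.
# Outcome group labels are the analysis units for subtype hazard ratios and
# for the trajectory network; groups must be pairwise disjoint.
exposure_codes: [F32, F41, F43]   # depression, anxiety, stress-related
outcome_groups:
  I10: [I10]   # hypertensive disease
  I20: [I20]   # angina pectoris
  I21: [I21]   # acute myocardial infarction
  I48: [I48]   # atrial fibrillation / flutter
  I50: [I50]   # heart failure
  I63: [I63]   # cerebral infarction
acute_event_codes: [I21, I63]
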