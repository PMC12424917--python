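# ICD-10 definitions of the analysis phenotypes: the 11 CVD subtypes with
# >= 10,000 UK Biobank cases, the Alzheimer's-disease outcome, and type 2
# diabetes (used as an adjustment covariate).
phenotypes:
  hypertension: "I10"
  hypotension: "I95"
  angina_pectoris: "I20"
  acute_myocardial_infarction: "I21"
  pulmonary_embolism: "I26"
  atrial_fibrillation: "I48"
  heart_failure: "I50"
  blockage: "I44"
  chronic_rheumatic_heart_disease: "I05-I09"
  chronic_ischemic_heart_disease: "I25"
  cerebral_infarction: "I63"
outcome:
  AD: "G30"
covariate_conditions:
  diabetes: "E11"
cvd_subtypes:
  - hypertension
  - hypotension
  - angina_pectoris
  - acute_myocardial_infarction
  - pulmonary_embolism
  - atrial_fibrillation
  - heart_failure
  - blockage
  - chronic_rheumatic_heart_disease
  - chronic_ischemic_heart_disease
  - cerebral_infarction
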