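# Published fixed-weight logistic model for COPD case assignment within a
# screen-positive datamart (curated features including spirometry).  Weights
# are data, not code: alternative or site-refit models are drop-in files with
# the same shape.
name: CRT_PFT_plus
intercept: -1.871
weights:
  everPFTlt70: 1.750
  nCOPDGTE3_365: 0.465
  everTiotropium: 0.334
  iNotWhite: -0.239
  smkEver: 0.175
  everdxAtPulmClinic: 0.056
  everCOPDmed: 0.048
  nmedLAMA: 0.017
  pftCount: -0.016
  ageCOPDt1Specific: 0.013
  nCOPD_ICD: 0.013
  nBronchitis: -0.009
  nBronchiectasis: -0.008
  patient_dxenct: -0.001
# Case assignment cutoff chosen holding specificity at 95% in the model's
# gold-standard training set; probabilities strictly above it are cases.
threshold: 0.754
# Fill rules applied before scoring when a feature is missing.
missing_policy:
  everPFTlt70: 0
  smkEver: 0
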