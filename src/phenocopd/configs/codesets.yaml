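# ICD prefix families used by the datamart filters and the model features.
# Each entry is [system, dotted prefix]; a prefix covers itself and all child
# codes (e.g. ICD9 "491.2" covers 491.2, 491.20, 491.21; ICD10 "J44" covers
# J44, J44.0, J44.1, J44.9).
codesets:
  # COPD-specific family: one such code makes a patient "screen positive".
  specific:
    - [ICD9, "491.2"]   # obstructive chronic bronchitis
    - [ICD9, "493.2"]   # chronic obstructive asthma
    - [ICD9, "496"]     # chronic airway obstruction, NEC
    - [ICD10, "J43"]    # emphysema
    - [ICD10, "J44"]    # other chronic obstructive pulmonary disease
  # Broad COPD family: the data-floor filter requires 3 of these on distinct
  # dates; control selection requires zero of them.
  broad:
    - [ICD9, "491"]     # chronic bronchitis
    - [ICD9, "492"]     # emphysema
    - [ICD9, "493.2"]
    - [ICD9, "496"]
    - [ICD10, "J40"]    # bronchitis, not specified as acute or chronic
    - [ICD10, "J41"]    # simple and mucopurulent chronic bronchitis
    - [ICD10, "J42"]    # unspecified chronic bronchitis
    - [ICD10, "J43"]
    - [ICD10, "J44"]
  # Feature families (counts of distinct diagnosis dates).
  copd_icd:
    - [ICD9, "491"]
    - [ICD9, "492"]
    - [ICD9, "493.2"]
    - [ICD9, "496"]
    - [ICD10, "J40"]
    - [ICD10, "J41"]
    - [ICD10, "J42"]
    - [ICD10, "J43"]
    - [ICD10, "J44"]
  bronchitis:
    - [ICD9, "490"]
    - [ICD9, "491"]     # 491 belongs to both copd_icd and bronchitis by design
    - [ICD10, "J40"]
    - [ICD10, "J41"]
    - [ICD10, "J42"]
  bronchiectasis:
    - [ICD9, "494"]
    - [ICD10, "J47"]
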