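# Medication vocabulary for the model's drug features.  Site-editable: the
# drug_name synonyms and class labels below match the synthetic generator's
# output and are meant to be extended with local formulary names.
medications:
  # drug_name substrings (case-insensitive) identifying tiotropium products
  tiotropium_names: [tiotropium, spiriva]
  # med_class labels counted as long-acting muscarinic antagonists
  lama_classes: [LAMA]
  # med_class labels meaning "a medication used to treat COPD"
  copd_med_classes: [COPD_med, LAMA]
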