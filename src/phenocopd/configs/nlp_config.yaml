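# Lexicons and negation handling for the two note-derived model features.
smoking:
  # Multi-word phrases are matched before single tokens.
  terms:
    - pack-year
    - pack year
    - pack-years
    - pack years
    - quit smoking
    - former smoker
    - current smoker
    - smoker
    - smoking
    - smokes
    - tobacco
    - cigarette
    - cigarettes
  # A term mention is negated when one of these cues appears within
  # `window` tokens immediately preceding it.
  negation_cues:
    - never
    - denies
    - denied
    - "no"
    - "not"
    - non
    - nonsmoker
    - non-smoker
  window: 4
  # When true, only notes with note_type == pft_report are scanned.
  restrict_to_pft_reports: false
spirometry:
  # Phase cue must precede the ratio token within the same section
  # (sections are blank-line separated).
  pre_cues: [pre-bronchodilator, pre bronchodilator, prebronchodilator, pre-bd]
  post_cues: [post-bronchodilator, post bronchodilator, postbronchodilator, post-bd]
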