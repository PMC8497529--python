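# Methods

## Problem and pipeline

COPD is under- and mis-diagnosed in routine care, so labeling patients from
EHR data is harder than matching a diagnosis code: spirometry (FEV1/FVC
< 0.7 after bronchodilators) is the confirmatory criterion but lives in
unstructured report text, and code counts alone have poor specificity. The
pipeline implemented here mirrors the screened-datamart paradigm: filter the
population to patients plausibly carrying COPD (screen-positive on specific
ICD codes), require a minimum information density (the data floor), then
apply a fixed-weight logistic classifier whose cutoff was chosen to hold
specificity near 95% — prioritizing positive predictive value, since
downstream association studies are conditional on correct case status.

Stages: flat-file ingest → code-set screening → NLP extraction → feature
construction → scoring → evaluation. Each stage is a pure function of
tables, exposed both as a library and as `phenocopd` subcommands.

## Code-set matching

ICD families are dotted prefixes with wildcard-child semantics. Matching
strips dots and accepts only digit tails: `491.2` covers `491.20`/`491.21`
but not a malformed `491.29x`; `J44` covers `J44.9`. The specific set (491.2,
493.2, 496; J43, J44) defines screening; the broad set adds 491\*, 492\*,
J40–J42 and defines the data floor and control exclusion. Whether `493.2`
covers its children 493.20–493.22 is implied but not settled in the source
listings; prefix semantics are adopted (a one-line YAML edit reverses this
at a site). Control "no history of COPD-related codes" is interpreted
against the broad family — the stricter reading, favoring control purity.

All counting uses distinct calendar dates per code *family*, not per
individual code: three codes on one day are one date, and duplicate rows at
ingest are deliberately retained (de-duplication is the counting operation's
job, keeping ingest lossless).

## NLP extraction

Only two model inputs come from text, and both are extracted with
deterministic regexes rather than a learned model: the grammar is portable,
auditable, and adds no training dependency.

* **FEV1/FVC**: the pattern family `FEV1 [/:] FVC [ratio] [of/=] <number>[%]`.
  Numbers above 2 are percentages (divided by 100); a true ratio cannot
  plausibly exceed 2 and a percentage cannot plausibly fall below 2, so the
  cut is unambiguous. Bronchodilator phase comes from the nearest preceding
  pre/post cue within the same blank-line-delimited section, else
  `unspecified`. Component volumes alone are never read as ratios.
* **Smoking**: a term lexicon (smoker, smoking, tobacco, pack-year,
  cigarettes, quit/former/current smoker) with a NegEx-style negation
  window: a cue (never, denies, no, not, non…) within 4 tokens before the
  term flips polarity. `smkEver = 1` iff any positive-polarity mention
  survives. Window size and both lexicons are config (`nlp_config.yaml`);
  all notes are scanned by default, with a switch to restrict to
  spirometry-report notes only.
* **Missing data**: a patient with no ratio anywhere — structured or
  extracted — gets `everPFTlt70 = 0`. This "missing ⇒ No" rule is
  load-bearing: it is what keeps the model computable on the large fraction
  of screen-positive patients who never had spirometry recorded. Strictly
  `< 0.7`: a ratio of exactly 0.70 is not low.

## Features

Fourteen features, computed per screen-positive patient, with the exact
definitions the weights were fitted against. Notable decisions:

* ICD-9 491 appears in both the COPD family (`nCOPD_ICD`) and the
  bronchitis family (`nBronchitis`); the double-counting is intentional and
  preserved, because the published weights assume it.
* `nCOPDGTE3_365` uses inclusive endpoints: three dates qualify when the
  last minus the first is ≤ 364 days. A sorted scan over runs of three
  consecutive distinct dates is equivalent to testing all triples.
* Age at first specific code is whole years with 365.25-day years
  (fractional age available behind a flag); it is an *error*, not a zero,
  when no specific code exists — the caller must pre-filter to the datamart.
* `pftCount` counts structured spirometry rows plus spirometry-report notes,
  de-duplicated per patient-date, because the flat schema carries no
  procedure codes. This is the main portability knob: a site with CPT codes
  should map them into either source table.
* Race compares case-insensitively to "White"; anything else, including
  missing, sets `iNotWhite = 1` with a log entry (no missing-race rule
  exists in the source definition; the weight itself likely reflects
  diagnostic disparity rather than biology and external validation never
  exercised it).
* Medication classes (which drugs are LAMAs or COPD medications) are a
  shipped, site-editable vocabulary (`meds_config.yaml`), seeded with
  tiotropium entries; `nmedLAMA` counts *distinct prescription codes*, not
  prescriptions.

## Classifier

The shipped `ModelSpec` (YAML) carries the published intercept −1.871, 14
weights and cutoff 0.754 verbatim; a checksum test guards the file. The
case rule is strictly `P > cutoff` — "above the cutoff" — fixed because the
boundary convention, though measure-zero, must be deterministic.

`select_threshold_at_specificity` returns the smallest cutoff whose
empirical specificity (fraction of gold non-cases at or below it) meets the
target; smallest-qualifying automatically maximizes sensitivity. A
sentinel candidate below the minimum score handles degenerate targets.

`fit_penalized_model` is a re-derivation utility, not the artifact's source
of validity (the original training data are private). It standardizes
features, fits elastic-net logistic regression with strength and l1-mixing
chosen by 5-fold cross-validated log loss over a log-spaced grid (the
original tuning grids are unpublished; these are this package's defaults),
optionally applies an adaptive stage — penalties re-weighted by the inverse
magnitude of an initial ridge fit, implemented by column rescaling since
scikit-learn exposes no per-feature penalties — and re-selects the cutoff at
95% specificity on the training labels. Its tests are property-based
(planted-signal recovery, null-label chance AUC), never weight-matching.

## Evaluation

Sensitivity/specificity/PPV/NPV are direct count ratios; a zero denominator
yields `None` plus a reason, never a silent 0 — material in small strata.
F_β = (1+β²)·PPV·sens / (β²·PPV + sens) with β = 1 and 0.5. AUC is the
rank statistic (ties count ½). Bootstrap CIs are percentile intervals over
B = 1000 patient-level resamples by default (flavor and B are choices; the
source states only "via bootstrap"), seeded and deterministic; resamples
with undefined metrics are dropped with a logged count, and more than 50%
undefined aborts. Cohen's kappa uses marginal-product expected agreement;
its significance test is out of scope. A reproduction check: the printed
validation confusion counts (33/51/3/13; 43/27/3/27; 103/9/68/2; 62/73/4/43)
regenerate every printed metric to 3 decimals — except F0.5 of the strict
rule, where exact arithmetic gives 0.6526 while 0.652 was evidently computed
from already-rounded PPV/sensitivity; tests allow one unit in the last
printed digit.

## Synthetic cohorts

The generator plants a case/non-case label and emits per-arm: Poisson
streams of COPD-family codes over follow-up, spirometry written *both* as
structured rows and as templated `FEV1/FVC: NN%` note text (so the NLP and
structured paths cross-check each other), smoking sentences in positive and
negated phrasings, tiotropium/LAMA and COPD medication records, encounters
and filler diagnoses. Defaults are the strong-signal study condition:
cases with sub-0.7 spirometry probability 0.9, smoking 0.9, tiotropium 0.6
and 4 COPD codes/year over 3 years versus 0.05 / 0.3 / 0.02 and 0.5/year
for non-cases; prevalence 0.4 (the chart-review mix of a screened
datamart); ages uniform 50–80, 85% White. `null_config()` makes the arms
identical, removing all signal. Six deterministic boundary patients
straddle each filter threshold (2 vs 3 broad-code dates; 364- vs 365-day
spans; 2 vs 1 encounters for control eligibility).

What it does *not* emulate: realistic note language (templated sentences
only), coding drift between ICD-9/10 eras, correlated comorbidity
structure, demographic margins of any real system, or miscoded events.
Passing tests therefore demonstrate pipeline correctness and planted-signal
recovery, not expected performance on real EHR data.

At the default strong-signal condition (n = 2000, seed 7) the shipped model
reaches sensitivity ≈ 0.91 and specificity ≈ 1.00 against the planted
truth, and chance AUC (≈ 0.5) under the null — both recomputed at run time
by the acceptance script and the test suite. Problem sizes used in tests
(n = 2000 end-to-end, 200 outer replications × 150 bootstrap resamples for
coverage) keep the full suite under two minutes while leaving Monte-Carlo
error comfortably inside the asserted bands.

## Known limitations

* Rule/regex NLP will miss ratio phrasings outside the implemented grammar
  and negations beyond a 4-token window; both lexicons are config for site
  tuning.
* The flat CSV schema is a deliberate simplification; no HL7/FHIR/OMOP
  ingestion, no ICD-9→ICD-10 crosswalk.
* The fitted AUC of the original model cannot be reproduced here (training
  data are private); only the validation arithmetic and the model's
  algebraic behavior are verifiable.
* Dirty system/code mismatches are flagged, not rejected — prefix matching
  operates regardless, as in the source filters.
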