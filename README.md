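# phenocopd

A portable computable phenotype for chronic obstructive pulmonary disease
(COPD) in electronic health records. The package is for epidemiologists and
biobank teams who need to label thousands of patients as COPD case / non-case
without manual chart review: it screens a flat-file EHR extract into a COPD
datamart with ICD code-set filters, pulls the two unstructured inputs the
model needs (FEV1/FVC ratios and smoking history) out of note text with
deterministic regular expressions, computes 14 patient-history features, and
scores them with a fixed-weight logistic model at a published
95%-specificity cutoff.

## The model

Screening: a patient enters the datamart with ≥ 1 COPD-*specific* ICD code
(ICD-9 491.2, 493.2, 496; ICD-10 J43\*, J44\*). A stricter *data floor*
(≥ 3 *broad* COPD-family codes — ICD-9 491\*, 492\*, 493.2, 496; ICD-10
J40\*–J44\* — on distinct dates, plus ≥ 1 clinical note) marks records rich
enough to phenotype. Two rule-based benchmarks (3-of and 2-of specific codes
on distinct dates) and a control-selection rule (zero broad-family codes,
≥ 2 encounters) are included.

Case assignment is logistic:

    lp = β₀ + Σᵢ βᵢ xᵢ ,   P(COPD) = 1 / (1 + e^(−lp)) ,   case ⇔ P > 0.754

with β₀ = −1.871 and 14 fixed feature weights, the largest being
`everPFTlt70` (+1.750): ever having spirometry with FEV1/FVC < 0.7 pre- or
post-bronchodilator. Other features include a rolling-window code-burst flag
(`nCOPDGTE3_365`: 3 COPD codes within any 365 days), tiotropium exposure,
smoking history, distinct-date counts of COPD / bronchitis / bronchiectasis
codes, pulmonary-clinic diagnoses, and utilization counts. Patients with no
spirometry anywhere get `everPFTlt70 = 0` ("missing ⇒ No"), which keeps the
model computable for every screen-positive patient. Weights are data, not
code: the shipped YAML can be swapped for site-refit weights, and
`fit_penalized_model` re-derives a model with (adaptive) elastic-net
logistic regression plus threshold re-selection at a target specificity.

Validation machinery covers confusion-matrix metrics with explicit
undefined-value handling, F1/F0.5, rank-based AUC, percentile bootstrap
confidence intervals, and Cohen's kappa for interrater agreement.

## Worked example

Every stage runs on seeded synthetic cohorts with planted COPD status — no
external data needed:

```sh
phenocopd simulate --n 500 --seed 7 --out cohort/
phenocopd run --cohort cohort/ --out-dir out/
phenocopd evaluate --gold cohort/truth.csv --pred out/scores.csv \
    --boot 500 --seed 7 --out report.json
```

which prints

```
wrote 500 patients to cohort/
wrote datamart, nlp_ratios, smoking, features, scores to out
{"sensitivity": 0.9123711340206185, "specificity": 0.993421052631579, "ppv": 0.9888268156424581, "npv": 0.9467084639498433}
```

Interpretation: of the 500 synthetic patients, 498 are screen-positive and
scored; the shipped model recovers 91% of planted cases while calling almost
no planted non-case a case (the synthetic arms are strongly separated, so
this is a pipeline check, not a clinical claim). `report.json` adds the
confusion counts and bootstrap 95% intervals for each metric.

The same thing in Python:

```python
from phenocopd import SimConfig, end_to_end_check

report, artifacts = end_to_end_check(SimConfig(n_patients=2000, seed=7))
print(report.sensitivity, report.specificity, report.auc)
# 0.906  0.997  0.995
```

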