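# bilinorm

Decision support and guideline-adherence auditing for neonatal
hyperbilirubinemia, aimed at clinicians and clinical researchers working
with threshold-nomogram guidelines (the stratified phototherapy /
exchange-transfusion kind used in Indonesia and adapted from the AAP and
NICE guidelines).

Severe newborn jaundice is treated by comparing the total serum bilirubin
(TSB, mg/dL) against age-dependent threshold curves: phototherapy (PT)
starts when TSB crosses the PT curve, and exchange transfusion is considered
when it crosses the higher exchange curve. The curves depend on the infant's
stratum — one nomogram for gestational age ≥ 35 weeks, four birth-weight
bands (≤1000, 1001–1499, 1500–1999, >1999 g) for preterm infants — and on
whether neurotoxicity risk factors (ABO/Rh incompatibility, haemolysis,
other illness, hypoalbuminemia) are present.

The package provides:

* **guideline_tables** — validated, versioned threshold-curve tables
  (piecewise-linear TSB vs postnatal age, clamped outside the knots).
  A clearly labelled placeholder default ships with the package; real
  guideline values drop in as a YAML file.
* **decision_engine** — patient record → stratum → nomogram placement →
  one of three advice tiers (`no_treatment`, `start_phototherapy`,
  `intensive_pt_consider_exchange`), plus a bilingual (en/id)
  family-education checklist.
* **neuro_scoring** — BIND-M acute bilirubin encephalopathy bands
  (0 / 1–4 / 5–6 / >6) and the 0–14 kernicterus spectrum disorder (KSD)
  risk bands (0–2 / 3–5 / 6–9 / 10–14).
* **adherence_audit** — chart-review engine classifying each treatment
  record as correct / over-treatment / under-treatment / inappropriate
  (PT without a TSB measurement), with pre/post epoch comparison by
  uncorrected Pearson chi-square, `χ² = Σ (O−E)²/E`.
* **questionnaire** — 7-point Likert acceptance-survey summaries
  (agreement rate = share of respondents at levels 6–7).
* **synthetic_cohort** — a seeded generator of two-epoch chart cohorts with
  known classification rates, and the packaged aggregate tables of the
  published two-hospital evaluation study.

## Worked example

A preterm girl born at 33 weeks (birth weight 2100 g) presents with jaundice
on day 2; blood tests show ABO incompatibility and TSB 17.2 mg/dL:

```bash
bilinorm recommend --ga 33 --bw 2100 \
    --birth 2019-03-01T08:00 --record 2019-03-03T08:00 \
    --tsb 17.2 --unit mg_dl --risk abo
```

```json
{
  "advice": "intensive_pt_consider_exchange",
  "stratum": "preterm_gt_1999",
  "risk_class": "with_risk",
  "age_hours": 48.0,
  "tsb_mg_dl": 17.2,
  "pt_threshold_mg_dl": 8.5,
  "et_threshold_mg_dl": 15.5,
  ...
}
```

At 48 h of age this infant falls in the preterm >1999 g stratum with risk
factors; her TSB (17.2) exceeds the exchange threshold of the shipped
default table (15.5), so the advice is to start intensive phototherapy
immediately and consider exchange transfusion. The same infant with mild
hypotonia and a high-pitched cry scores 2 on the BIND-M exam:

```bash
bilinorm score bind-m --mental 0 --tone 1 --cry 1 --gaze 0
```

```json
{
  "total": 2,
  "band": "mild_abe",
  "advice": "Mild ABE: probable low risk of neurological complications if appropriate treatment is provided timely."
}
```

Other subcommands: `bilinorm audit --charts charts.csv` (chart-review
classification + chi-square report), `bilinorm survey --counts table.csv`,
`bilinorm simulate --out charts.csv --seed 7`, `bilinorm fixtures`.

## Scope notes

The national guideline's numeric threshold values are not publicly printed;
the shipped default table is a documented placeholder (see
`docs/methods.md`), so recommendations are only as good as the threshold
table supplied. This package is a decision-support and audit library, not
medical advice.
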