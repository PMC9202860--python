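# Methods

## The decision model

Treatment advice for neonatal hyperbilirubinemia is a threshold comparison
on a nomogram: a piecewise-linear curve of total serum bilirubin (TSB,
mg/dL) against postnatal age (hours), one curve per intervention
(phototherapy, exchange transfusion) and risk class (no risk factors /
with risk factors), within one of five patient strata:

* gestational age ≥ 35.0 weeks → the term/near-term nomogram, regardless of
  birth weight;
* gestational age < 35 weeks → one of four birth-weight bands: ≤1000,
  1001–1499, 1500–1999, >1999 g (integer-gram boundaries as conventionally
  printed).

The value 35.0 exactly is assigned to the term stratum; guideline texts that
say "> 35" and "< 35" leave that point ambiguous and some convention must be
chosen once.

Given a record, the engine computes the exact postnatal age in hours,
converts TSB to mg/dL if reported in µmol/L (divide by 17.1, the molar
conversion for bilirubin), resolves the stratum and risk class, interpolates
both thresholds at that age, and emits the highest tier whose threshold is
met:

    TSB ≥ exchange threshold      → intensive PT + consider exchange
    TSB ≥ phototherapy threshold  → start phototherapy
    otherwise                     → no treatment

A TSB exactly equal to a threshold triggers the treatment — the conservative
reading, chosen because missing an indicated treatment is the costlier
error. Risk-factor semantics: declaring "no risk factors" is uncomplicated
hyperbilirubinemia (the higher, no-risk curves); any named factor *or*
"unknown" places the infant on the lower with-risk curves, because
unverifiable risk is treated as present.

### Threshold curves

Curves are ordered knot lists `(age_hours, tsb_mg_dl)` with at least two
knots, strictly increasing ages and positive TSB values. Lookups use linear
interpolation between knots and **clamp** to the terminal knot value outside
the knot span — deterministic and conservative (no extrapolated thresholds).
Loading validates eagerly, on a dense hourly grid over 0–336 h:

* exchange threshold ≥ phototherapy threshold within every (stratum, risk
  class);
* with-risk threshold ≤ no-risk threshold for every intervention.

Violations name the stratum and the first offending hour.

### The shipped default table is a placeholder

The national guideline's numeric nomogram values are not publicly printed.
The packaged default (`bilinorm/data/default_guideline.yaml`, version string
`placeholder-0.1`) is therefore package-authored: the term curves are shaped
like the AAP-2004-style nomogram that such guidelines adapt, and the four
preterm bands are age-ramped curves set progressively lower for smaller
infants. The file format is versioned YAML (schema in the module docstring
of `guideline_tables`), so real guideline values can be swapped in without
code changes. Every threshold-dependent result in this package — including
the worked example — should be read as conditional on the supplied table.

### Hypoalbuminemia cut-off

The risk-factor list includes hypoalbuminemia with the cut-off "<30 mg/L",
kept verbatim as a config constant. The conventional unit for serum albumin
is g/L (30 g/L = 3.0 g/dL), so the printed unit is likely a typo; it is
flagged here rather than silently corrected, and the constant is the single
place to change it.

## Neurological scoring

Two fixed band functions of an integer total:

* **BIND-M** (mental status, muscle tone, altered cry, altered gaze):
  total 0 → no ABE; 1–4 → mild; 5–6 → moderate; >6 → severe.
* **KSD** (highest TSB, risk factors, neurological exam at presentation and
  follow-up, enamel dysplasia, ABR, MRI; total 0–14): 0–2 → no kernicterus;
  3–5 → possible; 6–9 → probable; 10–14 → definite.

Published per-item rubrics differ between sources and are not reproduced
here; item maxima are configurable (defaults: BIND-M 3/3/2/1; KSD components
summing to 14), while the band cut-offs — which are the stable, published
part — are hard-coded. The band is a function of the total only, verified by
exhaustive sweeps and permutation tests.

## Adherence audit

Classification precedence, applied per record:

1. phototherapy given without any TSB measurement → **inappropriate**;
2. no TSB and no phototherapy → **unevaluable** (excluded from the four-way
   table, reported separately);
3. otherwise compare `pt_given` with the guideline indication
   (TSB ≥ PT threshold at the record's age/stratum/risk):
   agreement either way → **correct** (withholding when not indicated counts
   as correct), given-but-not-indicated → **over-treatment**,
   indicated-but-not-given → **under-treatment**.

Exchange transfusion is carried through the data model and reports but does
not enter the four-way classification, which is defined purely on the
phototherapy threshold. Multiple records per infant are audited per-record.

Epoch comparison uses Pearson's chi-square **without** Yates continuity
correction (`scipy.stats.chi2_contingency(correction=False)`): on the
published aggregate counts this reproduces all eight printed p-values
(0.006, 0.566, 0.234, 0.024 per category; 0.016 overall; 0.348, 0.786,
0.614 for the demographic tables) to three decimals, which the corrected
statistic does not. Categories with zero counts in both epochs are dropped
before testing (a degenerate expected cell); if only one category remains
there is no variation to test and the overall p-value is reported as null.
P-values are displayed to 3 decimals and percentages rounded half-up to
integers, mirroring the source tables' display.

## Questionnaire summaries

Survey items are 7-point Likert responses grouped into perceived usefulness,
perceived ease of use, subjective norm and intention to use. "Agreement" is
the share of respondents at levels {6, 7} (configurable); this choice
reproduces the study's headline rates (84% for the phototherapy-decision
item, 72% for ease of learning, n = 43) from the packaged counts. Display
percentages round half-up to integers. Note: a handful of the source
table's printed cell percentages are internally inconsistent with any single
rounding rule (e.g. 5/43 printed as 11 rather than 12, 2/43 as 4 rather
than 5 — apparently truncated); the package reports half-up consistently and
regression-tests the cells that are consistent.

## Synthetic cohorts

The generator emulates a two-epoch chart-review cohort. Defaults reproduce
the evaluation study's conditions: 255 pre- and 181 post-introduction
records; 52% of infants below 35 weeks; birth-weight and risk-factor
marginals matching the published demographic table; per-epoch category
rates 38/34/14/14% (pre) and 51/32/10/7% (post).

Construction is **classification-first**: each record first draws its
intended audit category, then builds a TSB value and treatment flags
consistent with that category relative to the supplied guideline — e.g.
"over-treatment" places the TSB strictly below the phototherapy threshold by
a positive margin (half-normal with scale `tsb_noise_sd`, default 1.5 mg/dL)
and sets `pt_given`. "Correct" records split evenly between
correctly-treated and correctly-withheld. A single `numpy` RNG stream per
cohort makes output byte-identical under a fixed seed. This design
guarantees the audit pipeline is testable end to end; the alternative — a
bilirubin-kinetics simulation — would add invented physiology without
improving what the tests can show.

What the generator does **not** emulate: bilirubin trajectories over time,
repeated measurements of one infant, correlation between gestational age and
birth weight, hospital-level clustering, or exchange-transfusion events.
Passing recovery tests therefore demonstrates the correctness of the
classification and tabulation machinery under known ground truth, not the
clinical realism of the records.

## Numerical and testing choices

* Chi-square correctness is cross-checked against an independent oracle — an
  explicit observed/expected double summation with the chi-square survival
  function evaluated through the regularized incomplete gamma function
  (`scipy.special.chdtrc`) — to 1e-10 on 1,000 random tables.
* Threshold interpolation is cross-checked against an explicit segment-walk
  evaluation to 1e-9 at 1,000 random ages.
* Rate-recovery tests compare mean audited rates over repeated seeds with
  the configured rates at a 3-binomial-SE tolerance; the acceptance script
  uses 200 cohorts of 436 records, which runs in a few seconds.
* Timestamps are ISO-8601 and timezone-naive inputs are compared directly
  (interpreted as local time); chart CSVs are UTF-8 with a decimal point
  regardless of locale.

## Known limitations

* The default threshold table is a placeholder, not the national
  guideline's values; do not use its numeric outputs clinically.
* Whether real guideline preterm curves differ by risk class or only shift
  is unknown; the table schema allows either.
* "Intensive" phototherapy is not modelled as a separate tier below the
  exchange threshold; the engine emits exactly the three advice strings the
  underlying tool defines.
* The audit is per-record; infants contributing several records are counted
  several times, as in the source analysis's denominators.
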