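# Placeholder default threshold table.
#
# The Indonesian national guideline's numeric nomogram values are not
# publicly printed; these curves are package-authored placeholders shaped
# like the AAP-2004-style term nomogram the guideline adapts, with
# age-ramped preterm birth-weight bands set lower than the term curves.
# Swap in real guideline values by pointing --guideline at a file with the
# same schema.  All thresholds are TSB in mg/dL against postnatal age in
# hours; lookups interpolate linearly and clamp outside the knot span.
name: bilinorm-placeholder-default
version: "placeholder-0.1"
strata:
  term_near_term:
    phototherapy:
      no_risk:   [[0, 7.0], [24, 11.0], [48, 13.5], [72, 15.5], [96, 17.0], [168, 18.0]]
      with_risk: [[0, 5.0], [24, 9.0], [48, 11.5], [72, 13.5], [96, 15.0], [168, 16.0]]
    exchange_transfusion:
      no_risk:   [[0, 14.0], [24, 19.0], [48, 22.0], [72, 24.0], [96, 25.0], [168, 25.0]]
      with_risk: [[0, 12.0], [24, 17.0], [48, 19.5], [72, 21.5], [96, 22.5], [168, 22.5]]
  preterm_gt_1999:
    phototherapy:
      no_risk:   [[0, 5.0], [24, 8.0], [48, 10.0], [72, 12.0], [96, 13.0], [168, 13.0]]
      with_risk: [[0, 4.0], [24, 6.5], [48, 8.5], [72, 10.0], [96, 11.0], [168, 11.0]]
    exchange_transfusion:
      no_risk:   [[0, 11.0], [24, 15.0], [48, 18.0], [72, 19.0], [96, 20.0], [168, 20.0]]
      with_risk: [[0, 9.0], [24, 13.0], [48, 15.5], [72, 17.0], [96, 17.5], [168, 17.5]]
  preterm_1500_1999:
    phototherapy:
      no_risk:   [[0, 4.0], [24, 7.0], [48, 9.0], [72, 10.0], [96, 11.0], [168, 11.0]]
      with_risk: [[0, 3.0], [24, 5.5], [48, 7.5], [72, 8.5], [96, 9.5], [168, 9.5]]
    exchange_transfusion:
      no_risk:   [[0, 10.0], [24, 13.0], [48, 15.0], [72, 16.0], [96, 17.0], [168, 17.0]]
      with_risk: [[0, 8.0], [24, 11.0], [48, 13.0], [72, 14.0], [96, 15.0], [168, 15.0]]
  preterm_1001_1499:
    phototherapy:
      no_risk:   [[0, 3.5], [24, 6.0], [48, 8.0], [72, 9.0], [96, 10.0], [168, 10.0]]
      with_risk: [[0, 2.5], [24, 4.5], [48, 6.5], [72, 7.5], [96, 8.5], [168, 8.5]]
    exchange_transfusion:
      no_risk:   [[0, 9.0], [24, 11.0], [48, 13.0], [72, 14.0], [96, 15.0], [168, 15.0]]
      with_risk: [[0, 7.0], [24, 9.0], [48, 11.0], [72, 12.0], [96, 13.0], [168, 13.0]]
  preterm_le_1000:
    phototherapy:
      no_risk:   [[0, 3.0], [24, 5.0], [48, 6.0], [72, 7.0], [96, 8.0], [168, 8.0]]
      with_risk: [[0, 2.0], [24, 4.0], [48, 5.0], [72, 6.0], [96, 7.0], [168, 7.0]]
    exchange_transfusion:
      no_risk:   [[0, 8.0], [24, 10.0], [48, 11.0], [72, 12.0], [96, 13.0], [168, 13.0]]
      with_risk: [[0, 6.5], [24, 8.5], [48, 9.5], [72, 10.5], [96, 11.5], [168, 11.5]]
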