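{
  "description": "Worked example: adjusted joint-exposure odds ratios for dichotomized Mediterranean-diet adherence x genetic risk score, from an eye-level logistic GEE analysis of an AMD case-control cohort (612 subjects, 1216 eyes). Diet is risk-coded (exposure = low adherence); joint reference category = high adherence & low GRS. or01 = high GRS alone, or10 = low adherence alone, or11 = both exposures.",
  "or01": 1.788,
  "or10": 2.327,
  "or11": 4.624,
  "or_diet_within_high_grs_risk_coded": 2.589,
  "or_diet_within_low_grs_risk_coded": 2.296,
  "n_subjects": 612,
  "n_eyes": 1216
}
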