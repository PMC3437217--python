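# Published per-clinic results from the four-clinic study (clinic-level rates
# are printed rounded to one decimal; denominators are exact counts). These are
# inputs for the pooled-aggregation worked examples and the analysis scripts;
# nothing in the engine reads them.
clinics: [FMC_A, FMC_B, FMC_C, FMC_D]

population:
  members: [123276, 149396, 196513, 116351]
  members_20plus: [95303, 120579, 143796, 77739]
  attendees_20plus: [45703, 53370, 46270, 28923]
  t2dm_patients: [7184, 6671, 7256, 4019]
  t2dm_total: 25130
  t2dm_share_of_attendees_pct: 14.4

patient_characteristics:
  mean_age: [62.9, 64.3, 61.8, 58.5]
  mean_age_total: 62.3
  mean_visits: [8.5, 9.6, 8.7, 7.9]
  mean_visits_total: 8.8

# Indicator rows: per-clinic denominators and printed percentages, plus the
# printed pooled percentage. A null rate means the clinic could not measure
# the indicator (no HbA1c laboratory capacity); such clinics still contribute
# their full denominator to the pooled total with a zero numerator.
# "reproducible" marks whether the printed pooled value is consistent with the
# printed per-clinic values under denominator-weighted pooling (the ACEi/ARB
# row's printed total is not; its printed pooled denominator also differs from
# the sum of the printed clinic denominators).
indicators:
  p1:
    denominators: [7184, 6671, 7256, 4019]
    rates: [9.0, 16.9, null, null]
    pooled_rate: 7.1
    reproducible: true
  p2:
    denominators: [7184, 6671, 7256, 4019]
    rates: [51.9, 28.2, 24.6, 5.4]
    pooled_rate: 30.3
    reproducible: true
  p3:
    denominators: [7184, 6671, 7256, 4019]
    rates: [22.2, 14.2, 7.0, 5.4]
    pooled_rate: 13.0
    reproducible: true
  p4:
    denominators: [3653, 3714, 4336, 2971]
    rates: [65.4, 54.7, 45.6, 70.0]
    pooled_rate: 57.8
    reproducible: true
  p5:
    denominators: [7184, 6671, 7256, 4019]
    rates: [1.8, 5.5, 4.9, 3.0]
    pooled_rate: 3.9
    reproducible: true
  p6:
    denominators: [5066, 4437, 5216, 2840]
    rates: [57.2, 63.0, 66.7, 67.6]
    pooled_rate: 63.2
    reproducible: true
  p7:
    denominators: [4545, 4536, 4298, 1787]
    rates: [46.0, 56.8, 58.9, 66.1]
    pooled_rate: 57.4
    reproducible: false
  p8:
    denominators: [5242, 5035, 4904, 2076]
    rates: [45.8, 32.0, 46.2, 58.9]
    pooled_rate: 43.4
    reproducible: true
  p9:
    denominators: [2436, 1998, 2197, 1233]
    rates: [55.6, 43.9, 49.1, 36.9]
    pooled_rate: 47.9
    reproducible: true
  o1:
    denominators: [4644, 3560, 4563, 2816]
    rates: [23.0, 32.5, 19.2, 17.9]
    pooled_rate: 23.1
    reproducible: true
  o2:
    denominators: [5097, 4168, 4125, 3008]
    rates: [52.2, 52.1, 46.7, 59.0]
    pooled_rate: 52.0
    reproducible: true
  o3:
    denominators: [7088, 6587, 7247, 4011]
    rates: [12.3, 8.5, 14.1, 5.7]
    pooled_rate: 10.8
    reproducible: true
  o4:
    denominators: [5066, 4437, 5216, 2840]
    rates: [13.4, 14.7, 12.6, 12.5]
    pooled_rate: 13.3
    reproducible: true
  o5:
    denominators: [4272, 3123, 3479, 2516]
    rates: [1.8, 1.7, 1.2, 0.6]
    pooled_rate: 1.4
    reproducible: true
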