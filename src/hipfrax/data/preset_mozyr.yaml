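# Default synthetic-registry preset: a Mozyr-like two-year survey.
# Expected qualifying counts: ~76 female, ~41 male over 2011-2012.
observation_years: 2.0
population:
  female: [4951, 4530, 3371, 2212, 2107, 1896, 1159, 843]
  male: [3883, 3451, 2445, 1582, 1294, 1007, 503, 215]
incidence:
  female: {h0: 1.2374e-4, gamma: 0.125}
  male: {h0: 2.6778e-4, gamma: 0.098}
hospitalization: {intercept: 1.65, age_slope: -0.09, female_offset: -0.4}
p_high_energy: 0.10
p_pathological: 0.04
p_nonresident: 0.06
p_under50: 0.05
p_duplicate: 0.05
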