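# Default 18-indicator deprivation schema for the Extreme Climate
# Vulnerability Index.  Dimensions carry equal weight (1/3 each);
# indicators share their dimension's weight equally.
#
# Rules: upper_quartile -> deprived iff value >= cross-region Q3
#        lower_quartile -> deprived iff value <= cross-region Q1
#        below_absolute -> deprived iff value < threshold (strict)
#
# The income threshold is monthly per-capita income in 2010 BRL;
# 296.8 is the packaged default, 255.00 (half the 2010 minimum wage)
# a documented alternative preset.
indicators:
  # --- exposure: extreme-climate indices ---
  - {id: txx,   dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: tnx,   dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: tx90p, dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: tn90p, dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: dtr,   dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: cdd,   dimension: exposure, rule: upper_quartile, weight: 1/21}
  - {id: r99p,  dimension: exposure, rule: upper_quartile, weight: 1/21}
  # --- susceptibility: sociodemographic ---
  - {id: prop_elderly,      dimension: susceptibility, rule: upper_quartile, weight: 1/15}
  - {id: prop_children,     dimension: susceptibility, rule: upper_quartile, weight: 1/15}
  - {id: income_per_capita, dimension: susceptibility, rule: below_absolute, weight: 1/15, threshold: 296.8}
  - {id: prop_poor,         dimension: susceptibility, rule: upper_quartile, weight: 1/15}
  - {id: prop_literate,     dimension: susceptibility, rule: lower_quartile, weight: 1/15}
  # --- adaptive capacity: infrastructure & health supply ---
  - {id: prop_sewage,            dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
  - {id: prop_water,             dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
  - {id: prop_garbage,           dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
  - {id: urbanization,           dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
  - {id: primary_care_coverage,  dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
  - {id: hospital_beds_per_100k, dimension: adaptive_capacity, rule: lower_quartile, weight: 1/18}
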