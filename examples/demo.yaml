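alpha1: 0.05
chain_alpha: 0.05
discordance_threshold: 0.75
eqtl_alpha: 0.05
instrument_p_max: 5.0e-08
pp_threshold: 0.75
r2_max: 0.1
sex_stratified: true
sim:
  age_effect_pe: 0.1
  age_range:
  - 40.0
  - 80.0
  architectures:
  - shared
  - shared
  - 'null'
  - 'null'
  - 'null'
  - 'null'
  ge_h2: 0.2
  independent_r2_cap: 0.05
  ld_decay: 0.7
  maf_range:
  - 0.15
  - 0.5
  mediation_fraction: 1.0
  n_regions: 6
  n_samples: 1600
  n_tissues: 2
  n_variants_per_region: 16
  pathway_coupling: 0.0
  pe_h2: 0.2
  prevalence: 0.3
  seed: 101
  sex_effect_pe: 0.2
  sex_interaction: 1.0
  sign_patterns:
  - discordant
  - discordant
  - concordant
  - concordant
  - concordant
  - concordant
  theta_ge_direct: 0.3
  theta_pe: 0.8
split_fractions:
- 0.22
- 0.22
- 0.22
- 0.34
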