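simulate:
  populations:
    - {name: NBR, n_founders: 80, n_generations: 3, n_sires: 42,
       sire_mean: 4.4, sire_sd: 3.5, dam_mean: 3.4, dam_sd: 2.1}
    - {name: RM, n_founders: 90, n_generations: 3, n_sires: 43,
       sire_mean: 3.9, sire_sd: 3.3, dam_mean: 2.4, dam_sd: 1.3}
  n_chromosomes: 4
  markers_per_chromosome: 8
  female_male_ratio: 1.12
  typing_success: 0.95
  error_rate: 0.005
  seed: 42
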