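# Published YerA41 study constants; the pipeline's default configuration.
name: yera41_paper
geometry:
  h: 4
  k: 2
rise_per_bp_nm: 0.34
capsids:
  YerA41-B:
    internal_volume_nm3: 620000.0
    genome_length_bp: 145577
    copies: [1, 2]
  YerA41-S:
    internal_volume_nm3: 270000.0
    genome_length_bp: 145577
    copies: [1]
shells:
  min_prominence: 0.1
  min_separation_A: 15.0
composition:
  expected_t_percent: 34.0
  observed_t_percent: 15.0
  pairing_tolerance: 0.25
ms:
  tolerance: 0.5
  min_ladder_length: 2
mass_model:
  genome_length_bp: 145577
  at_bp: 98567
  substitution_fraction: 0.56
  bp_mass_da: 618.0
  mod_mass_da: 1044.0
reference_density_bp_nm3: 0.54
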