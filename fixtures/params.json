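{
  "bio_contaminant_trace": 5.0,
  "bird_concentration": 300.0,
  "blank_rate": 80.0,
  "condition_coupling": 0.04,
  "convergence": 0.85,
  "diversity_drop": 0.4,
  "firmicutes_up": 2.0,
  "mass_noise_sd": 0.012,
  "mean_mass_d15": 18.0,
  "mean_mass_d8": 12.0,
  "mean_tarsus": 19.3,
  "n_blanks": 4,
  "n_cf_pairs": 1,
  "n_contaminants": 12,
  "n_negative_controls": 3,
  "n_nests": 4,
  "n_otus": 100,
  "negative_control_depth": 1500,
  "negative_gain_fraction": 0.025,
  "negative_real_trace": 2.0,
  "nest_concentration": 20.0,
  "nest_env_weight": 0.6,
  "nestlings_per_nest": 6,
  "phyla_d8": {
    "Actinobacteria": 0.3,
    "Bacteroidetes": 0.1,
    "Firmicutes": 0.3,
    "Proteobacteria": 0.25,
    "Tenericutes": 0.05
  },
  "proteobacteria_down": 0.35,
  "seed": 1,
  "sequencing_depth": 3000,
  "size_sd": 0.04,
  "sma_slope": 1.87,
  "tarsus_noise_sd": 0.008
}
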