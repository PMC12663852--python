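{
  "seed": 42,
  "simulate": {
    "n_samples": 400,
    "mix_high": 0.43,
    "mu_low": 0.0,
    "mu_high": 3.0,
    "sigma": 1.0,
    "n_genes": 2000,
    "signature_size": 125,
    "senescence_d": 0.6,
    "coupling_rho": -0.57,
    "tmb_mean_low": 2.0,
    "tmb_mean_high": 3.2,
    "tmb_dispersion": 3.0,
    "cna_mean_low": 0.25,
    "cna_mean_high": 0.315,
    "loh_mean_low": 0.15,
    "loh_mean_high": 0.25,
    "tl_median_low": 1.1,
    "tl_median_high": 0.9,
    "clinical_or": {"sex_female": 2.0},
    "include_cells": false
  },
  "stratify": {"n_iter": 100, "n_init": 10},
  "score": {"method": "ssgsea", "alpha": 0.25},
  "compare": {"tl_test": "wilcoxon"},
  "rules": {"age_scheme": "clinical"}
}
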