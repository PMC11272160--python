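{
  "seed": 1,
  "bulk": {
    "synthetic": {
      "timepoints_hr": [0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0],
      "n_replicates": 3,
      "n_genes_total": 2000,
      "activation_fold": 8.0,
      "nb_dispersion": 0.05
    }
  },
  "thresholds": {"fdr_max": 0.05, "min_abs_fold": 2.0},
  "stringent": "none",
  "projection": {
    "synthetic_atlas": {
      "n_cells": 1500,
      "cluster_separation": 10.0,
      "within_cluster_sd": 0.5
    },
    "n_components": 30,
    "n_cells": 100,
    "k_neighbors": 15
  }
}
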