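{
  "time_course": {
    "n_genes_total": 2000,
    "n_replicates": 3,
    "activation_fold": 8.0,
    "nb_dispersion": 0.05,
    "seed": 1
  },
  "atlas": {
    "n_cells": 1500,
    "cluster_separation": 10.0,
    "within_cluster_sd": 0.5,
    "seed": 2
  }
}
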