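{
  "class_counts": {
    "convergent_2": 8,
    "convergent_3": 2,
    "convergent_4": 2,
    "lineage_specific": 12,
    "none": 16
  },
  "combination_counts": {
    "caecilian": 4,
    "caecilian+lizard_A+lizard_B+snake": 2,
    "caecilian+lizard_A+snake": 2,
    "caecilian+lizard_B": 1,
    "caecilian+snake": 6,
    "lizard_A": 2,
    "lizard_A+snake": 1,
    "lizard_B": 2,
    "snake": 4
  },
  "limb_gene_enrichment": {
    "caecilian+lizard_A": {
      "odds_ratio": 12.4286,
      "q_value": 0.125068
    },
    "caecilian+lizard_B": {
      "odds_ratio": 1.5556,
      "q_value": 1.0
    },
    "caecilian+snake": {
      "odds_ratio": 261.0,
      "q_value": 2e-06
    },
    "lizard_A+lizard_B": {
      "odds_ratio": 3.2222,
      "q_value": 0.530769
    },
    "lizard_A+snake": {
      "odds_ratio": 6.0,
      "q_value": 0.178575
    },
    "lizard_B+snake": {
      "odds_ratio": 3.2222,
      "q_value": 0.530769
    }
  },
  "mc_overlap": {
    "mean": 20.9447,
    "n_trials": 20000,
    "observed_overlap": 49,
    "sd": 3.991571,
    "universe_size": 800,
    "z_score": 7.0286
  },
  "n_calls_degenerated": 117,
  "n_cnes_retained": 40,
  "n_cnes_simulated": 40,
  "n_convergent": 12,
  "n_dcnes": 24,
  "n_limbless": 12,
  "n_species": 43,
  "neutral_group_means": {
    "convergent_dcne": 0.727859,
    "neutral": 0.751734,
    "non_dcne": 0.997306
  },
  "origin_counts": {
    "gnathostome_ancestor": 17,
    "lungfish_tetrapod_ancestor": 2,
    "osteichthyan_ancestor": 11,
    "sarcopterygian_ancestor": 4,
    "tetrapod_ancestor": 6
  },
  "pleiotropic_fraction": 0.6364,
  "rates_per_myr": {
    "caecilian_1": 0.0573,
    "caecilian_2": 0.0573,
    "caecilian_3": 0.0573,
    "caecilian_4": 0.0,
    "lizard_A_1": 0.125,
    "lizard_B_1": 0.0857,
    "snake_1": 0.0647,
    "snake_2": 0.0647,
    "snake_3": 0.0647,
    "snake_4": 0.0647,
    "snake_5": 0.0,
    "snake_6": 0.0
  },
  "seed": 1
}
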