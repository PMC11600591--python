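# demo run conditions: a 40-element cohort under the default detection
# thresholds, 10 neutral replicates per element, 20,000 Monte Carlo trials
simulate:
  n_cnes: 40
  deletion_every: 5
neutral:
  n_replicates: 10
introns:
  n_trials: 20000
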