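# Demo configuration for `tcrtrack run` — a scaled-down stimulation time
# course that completes end to end in well under a minute on one CPU.
seed: 42

simulate:
  n_clones: 500
  depth: 8000
  timepoints: [0, 3, 5, 10]
  n_replicates: 3
  responder_fraction: 0.05
  dispersion: 0.05
  sort_enrichment: 20.0
  activation_link: 0.8

sizedist:
  depth: 5000

cluster:
  k: 8
  restarts: 25
  min_replicates: 2
  presence_mode: any

diffexp:
  fc_cut: 1.5
  alpha: 0.05
  prior_weight: 10.0
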