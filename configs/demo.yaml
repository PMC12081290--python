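# Demo run: a full synthetic session with a 200-unit mixed population.
# Produces trials/spikes, epoch-rate matrices, cross-maze classification
# with shuffle attribution, single-cell + schema-ensemble decoding, and
# the population-geometry stage.  Takes a few minutes on one CPU.
seed: 1
out_dir: runs/demo

session:
  trials_per_type: 20
  n_units: 200
  category_mix: [0.4, 0.3, 0.3]   # schema-like, nonschema-like, noncoding-like

classify:
  r_schema: 0.8
  r_noncoding: 0.4
  alpha_corr: 0.01
  n_shuffles: 1000
  shuffle_percentile: 99

decode:
  n_single_units: 10
  single_repeats: 1000
  ensemble_units: 50
  ensemble_repeats: 200
  ensemble_trials_per_type: 15

geometry:
  tca_rank: 6
  tca_restarts: 5
  n_neighbors: 19
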