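# Branched-pathway demo: simulate noisy x2/x3 time courses, fit the
# two-output dependent GP, predict derivatives and estimate fluxes v2/v3.
seed: 0
data:
  generator:
    name: branched_pathway
    obs_times: [0.0, 0.33, 0.66, 1.0, 1.33, 1.66, 2.0, 2.33, 2.66, 3.0,
                3.33, 3.66, 4.0, 4.33, 4.66, 5.0, 5.33, 5.66, 6.0, 6.33,
                6.66, 7.0, 7.33, 7.66, 8.0]
model:
  kind: two_output
  outputs: [x2, x3]
center: true
optimizer:
  n_starts: 6
  max_iter: 2000
prediction:
  hyper_draws: 30
test_grid:
  start: 0.8
  stop: 7.2
  num: 50
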