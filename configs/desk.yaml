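# Desk-scale profile: minutes per scenario on one CPU.
generator:
  population_size: 50000
  seed: 0
sizes: [500, 1000]
proportions: [0.1, 0.2, 0.3, 0.4, 0.5]
mechanisms: [MCAR, MAR, MNAR]
engines: [pmm, polr, polyreg, rf, jm, cca]
mar_weights:
  event: 0.5
  nelson_aalen: 0.5
  stage: 0.3
  age: 0.2
  intention: -0.3
n_sim: 100
seed: 0
workers: 1
out_dir: results/desk
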