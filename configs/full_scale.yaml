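# Full-scale profile: the complete factorial design at its published
# replication count.  A multi-day computation on a single CPU; use --workers.
generator:
  population_size: 50000
  seed: 0
sizes: [500, 1000, 5000]
proportions: [0.1, 0.2, 0.3, 0.4, 0.5]
mechanisms: [MCAR, MAR, MNAR]
engines: [pmm, polr, polyreg, rf, jm, cca]
mar_weights:
  event: 0.5
  nelson_aalen: 0.5
  stage: 0.3
  age: 0.2
  intention: -0.3
n_sim: 1000
seed: 0
workers: 1
out_dir: results/full_scale
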