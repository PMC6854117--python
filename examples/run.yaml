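# Desk-scale end-to-end run: simulate a fixture, then push it through every
# analysis stage.  All numbers here are deliberately small; raise scale,
# sims and permutation counts for real runs.
stages: [simulate, sfs, stats, fit, abc, fdist, report]
seed: 1
outdir: runs/desk

simulate:
  preset: model3
  scale: 0.02          # fraction of the full 2,869 capture regions

sfs:
  pops: [DT, CH, SH]

stats:
  fst_permutations: 200
  amova_permutations: 500

fit:
  pops: [DT, CH, SH]
  models: [model1, model2, model3]
  runs: 2
  sims: 500
  cycles_min: 3
  cycles_max: 6

abc:
  model: model3
  pops: [CH, SH]
  nsims: 300
  naccept: 30
  npls: 3
  method: loclinear
  priors:
    T3: [200.0, 20000.0, true]   # low, high, log-scale

fdist:
  pops: [DT, SH]
  nsims: 4000
  tune_sims: 1000
  tol: 0.01
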