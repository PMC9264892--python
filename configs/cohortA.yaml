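# Design A: 100 cancers vs 100 healthy controls, balanced -> no resampling.
# Full-size run (51 splits, 1000 permutation iterations): expect hours.
cohort:
  n_cases: 100
  n_controls: 100
  effect_size: 4.0     # strong class effect (healthy-control contrast)
  seed: 1001
models: [rf, plsda, svm_linear]
n_repeats: 51
sampling: none
perm_iters: 1000
base_seed: 1
outdir: results/cohortA
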