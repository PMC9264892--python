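# Scaled-down design-A demo: same structure, desk-scale sizes
# (15 vs 15 patients, 3 splits, 100 permutation iterations; ~1 min).
cohort:
  n_cases: 15
  n_controls: 15
  effect_size: 4.0
  seed: 1001
models: [rf, plsda, svm_linear]
n_repeats: 3
sampling: none
perm_iters: 100
base_seed: 1
outdir: results/cohortA_demo
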