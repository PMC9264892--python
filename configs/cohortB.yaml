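# Design B: 35 cancers vs 35 symptomatic controls, balanced.
# Symptomatic controls are harder to separate -> moderate effect.
cohort:
  n_cases: 35
  n_controls: 35
  effect_size: 1.5
  seed: 1002
models: [rf, plsda, svm_linear]
n_repeats: 51
sampling: none
perm_iters: 1000
base_seed: 2
outdir: results/cohortB
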