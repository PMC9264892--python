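# Design C: 100 cancers vs 35 symptomatic controls, imbalanced -> SMOTE.
cohort:
  n_cases: 100
  n_controls: 35
  effect_size: 1.5
  seed: 1003
models: [rf, plsda, svm_linear]
n_repeats: 51
sampling: smote
perm_iters: 1000
base_seed: 3
outdir: results/cohortC
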