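# Full two-stage pipeline configuration.
# Paths point at the cohort written by examples/simulate_cohort.py or
# examples/run_full_pipeline.py.

seed: 42                      # master seed; every stochastic stage derives its own
ct_path: scratch/example_cohort/ct.tsv
samples_path: scratch/example_cohort/samples.tsv
output_dir: scratch/example_run

control_id: RNU48             # endogenous-control assay for deltaCt
max_cycles: 40                # detection limit in cycles
impute_censored: true         # censored wells -> deltaCt at the limit
detect_threshold: 0.30        # >=30% detected in either group
screen_alpha: 0.05            # Wilcoxon screen threshold
screen_method: auto           # exact when n<=10 and tie-free, else asymptotic
alpha_enter: 0.10             # stepwise alpha-to-enter
alpha_remove: 0.15            # stepwise alpha-to-remove
classifiers: [logistic, svm_linear]
cutoff: 0.5                   # probability cutoff for accuracy
adjust: true                  # also report confounder-adjusted variants
n_perm: 1000                  # label permutations per set
subset_k: [7]                 # random-subset null model sizes
n_draws: 2000                 # subset draws
testing_mode: refit           # refit | frozen coefficients on the testing set
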