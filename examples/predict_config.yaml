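# Configuration for `gutresponder predict --config <this file>`.
# Every key is optional; omitted keys keep the defaults shown here.

# Feature-filter grid: a feature is kept when its mean value over the
# TRAINING samples is strictly above the threshold.
genus_thresholds: [0.0, 0.01]        # relative-abundance thresholds
metabolite_thresholds: [10.0, 100.0] # content thresholds (ignored when no
                                     # metabolite table is supplied)

# LASSO penalty grid for the feature-selection step.
alphas: [0.0001, 0.001]

# Stratified cross-validation: `folds`-fold, partitions resampled
# `repeats` times with seeded shuffling.
folds: 7
repeats: 10
seed: 0
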