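"""Predict responders from baseline features with the LASSO -> logistic
pipeline.

A synthetic cohort of 40 subjects has 5 informative genera (of 60) whose
baseline abundance tracks the individual supplement effect.  The pipeline
grid-searches abundance thresholds and the LASSO penalty under 7-fold
stratified cross-validation repeated over 10 partitions, scoring each grid
point by the partition-averaged AUROC of pooled out-of-fold predictions.
"""

import numpy as np
import pandas as pd

from gutresponder import MLGrid, cross_validated_grid_search

rng = np.random.default_rng(0)
n, n_features, n_informative = 40, 60, 5
labels = (rng.random(n) < 0.5).astype(int)          # responder = SR or WR
y_effect = np.where(labels == 1, rng.normal(1.0, 0.3, n),
                    rng.normal(-1.0, 0.3, n))        # posterior-mean effect
X = rng.lognormal(mean=-2.0, sigma=1.0, size=(n, n_features))
X[:, :n_informative] *= np.exp(2.0 * y_effect[:, None])
genus = pd.DataFrame(X / X.sum(axis=1, keepdims=True),
                     columns=[f"g{j}" for j in range(n_features)],
                     index=[f"s{i}" for i in range(n)])

grid = MLGrid(genus_thresholds=(0.0, 0.01), metabolite_thresholds=(),
              alphas=(0.001, 0.01))
best, results = cross_validated_grid_search(
    {"genus": genus}, labels, y_effect, grid, k=7, repeats=10, seed=0
)

print("grid point                                    AUROC  accuracy  F")
for r in results:
    print(f"{str(r.grid_point):44s} {r.mean_auroc:.3f}   "
          f"{r.mean_accuracy:.3f}   {r.mean_f_measure:.3f}")
best_res = next(r for r in results if r.grid_point == best)
sel_rate = np.mean([
    bool(set(f"g{j}" for j in range(n_informative)) & set(s))
    for s in best_res.selected_features
])
print(f"\nbest grid point: {best}")
print(f"averaged AUROC {best_res.mean_auroc:.3f}; an informative feature "
      f"was selected in {100 * sel_rate:.0f}% of training folds.")
print("AUROC near 1 means baseline features rank responders above "
      "non-responders almost perfectly; 0.5 would be chance.")
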