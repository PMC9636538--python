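# gutresponder

Quantifying **individual** response to a probiotic supplement from
crossover-trial defecation diaries, and predicting who will respond from
baseline gut microbiome and metabolome profiles.

Probiotic trials often report an average effect on bowel-movement frequency,
yet the response varies strongly between people. `gutresponder` implements a
statistical pipeline for that individual-level question, for biostatisticians
and microbiome researchers working with randomized double-blind
placebo-controlled crossover designs:

1. **Interval model.** Daily defecation counts are expanded into
   bowel-movement intervals (a day with `f` movements splits 24 h into
   intervals of `24/f` h). The interval `I_{s,i}` of subject `s` follows a
   Weibull distribution in proportional-hazards form,

   ```
   I_{s,i} ~ Weibull(k_s, λ_{s,i}),          hazard  h(t) = k_s λ_{s,i} t^{k_s − 1}
   λ_{s,i} = exp(gut_state_s + β_{s,placebo} + β_{s,test})   on test-supplement days
           = exp(gut_state_s + β_{s,placebo})                on placebo days
           = exp(gut_state_s)                                otherwise
   ```

   with hierarchical priors `k_s ~ HalfNormal(0, σ_k)`,
   `gut_state_s ~ Normal(0, σ_gut_state)`,
   `β_{s,placebo} ~ Normal(0, σ_placebo)`, `β_{s,test} ~ Normal(0, σ_test)`.
   A positive `β_{s,test}` raises the hazard: shorter intervals, more
   frequent bowel movements. Posteriors are sampled by NUTS (Hamiltonian
   Monte Carlo) with split-chain rank-normalised R̂ convergence checks;
   Poisson daily-count and Bernoulli daily-indicator variants are available,
   and effect structures (none / shared / individual) are compared by WAIC.
2. **Responder classification.** Subject `s` is a strong responder (SR) when
   the 2.5% bound of the 95% credible interval of `β_{s,test}` is above zero,
   a weak responder (WR) when only the posterior mean is above zero, and a
   non-responder (NR) otherwise. Subjects whose intervals carry no variance
   (e.g. exactly one movement a day throughout) are excluded.
3. **Responder features.** Shannon alpha diversity; Spearman-correlation
   beta diversity with classical MDS; paired Wilcoxon signed-rank tests with
   Benjamini–Hochberg FDR; a crossover carry-over check; within-subject
   responder scores `((T2−T1) − (C2−C1)) / mean(C1, T1)`; baseline fold
   changes FCs (SR/NR) and FCw (WR/NR) screened by the ordering rule
   `FCs > FCw > 1` or `FCs < FCw < 1` and a two-sided Jonckheere–Terpstra
   trend test across NR < WR < SR.
4. **Responder prediction.** From baseline (T1) features: abundance
   filtering → z-scoring → LASSO selection against the posterior-mean
   `β_{s,test}` → L2 logistic classification of responders (SR ∪ WR) vs NR,
   evaluated by 7-fold stratified cross-validation repeated over 10
   partitions with a grid search (AUROC / accuracy / F-measure). All
   data-dependent steps are fitted on training folds only.
5. **Synthetic trials.** A condition-dependent Weibull renewal simulator and
   a feature-table simulator with planted responder structure make the whole
   pipeline testable end-to-end without clinical data.

The NUTS sampler and all statistics above are implemented in the package
itself (numpy/scipy/pandas); scikit-learn provides the LASSO/logistic fits
and statsmodels the FDR correction.

## Worked example

```sh
python examples/simulate_and_classify.py
```

simulates a 10-subject crossover trial, fits the individual-effects model
(4 chains × 2,000 iterations) and prints:

```
7 fittable subjects; excluded (too few events or zero interval variance): ['S07', 'S08', 'S09']
max split-chain Rhat = 1.0022 (convergence requires <= 1.1)

subject    label  posterior_mean  ci_2.5%  ci_97.5%  true_beta_test
    S01       WR           0.024   -2.160     2.227           1.071
    S02       WR           0.274   -0.396     0.968          -0.203
    S03       WR           0.019   -1.995     2.206          -0.256
    S04       NR          -1.090   -1.939    -0.359          -0.407
    S05       SR           0.836    0.274     1.438           0.308
    S06       WR           0.744   -0.580     2.006           0.564
    S10       WR           0.460   -0.700     1.546           0.325
    S07 excluded             NaN      NaN       NaN          -0.057
    S08 excluded             NaN      NaN       NaN          -0.420
    S09 excluded             NaN      NaN       NaN          -0.412
```

Each row compares the posterior of that subject's supplement effect with
zero: `S05` is called a strong responder because even the lower credible
bound is positive, while `S04`'s negative posterior mean makes it a
non-responder. The `true_beta_test` column shows the generating values the
fit is recovering; subjects with wide credible intervals had few events to
learn from. Further examples: `examples/model_comparison.py` (WAIC
ranking of the five effect structures), `examples/feature_statistics.py`
(diversity, MDS, carry-over, fold-change/trend screen) and
`examples/predict_responders.py` (cross-validated grid search, averaged
AUROC ≈ 0.98 on a planted-signal cohort).

A thin CLI wraps the same functions for shell pipelines:
`gutresponder simulate | fit | compare | classify | features | predict |
report` (see `gutresponder --help`).

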