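# Methods

## The interval model

Bowel movements are treated as a renewal process: the waiting time
`I_{s,i}` between the (i−1)-th and i-th movement of subject `s` is Weibull
distributed with subject-specific shape `k_s` and an observation-specific
rate determined by the condition in force,

    log f(t | k, η) = log k + η + (k − 1) log t − exp(η) t^k,

which is the proportional-hazards (rate) parameterisation with hazard
`h(t) = k e^η t^{k−1}`. The linear predictor η stacks three terms:

| term            | active on                | prior                        |
|-----------------|--------------------------|------------------------------|
| `gut_state_s`   | every day                | Normal(0, σ_gut_state)       |
| `β_{s,placebo}` | placebo **and** test days| Normal(0, σ_placebo)         |
| `β_{s,test}`    | test days only           | Normal(0, σ_test)            |

so the test effect is measured *on top of* the placebo response.
`k_s ~ HalfNormal(0, σ_k)`; all four scale hyperparameters get HalfNormal(0, 1)
hyperpriors (the original model statement leaves them open; half-normal unit
scales are the standard weakly-informative choice for hierarchical scales).
In this parameterisation a positive `β_{s,test}` multiplies the hazard by
`e^{β}` and stochastically shortens intervals — the sign convention under
which a responder has *more frequent* bowel movements. The equivalent
standard-scale Weibull has scale `σ = λ^{−1/k}`.

Intervals are measured in **days**, so typical log-rates sit near zero,
matching the Normal(0, σ) centring of `gut_state`.

Two coarser families share the same linear predictor: daily counts as
Poisson with log-rate η, and daily presence/absence as Bernoulli with
logit η. Effect structure is configurable per term — `none`, `shared`
(one scalar across subjects, prior Normal(0, 1)) or `individual`
(hierarchical) — giving the five-variant Weibull family used for model
comparison: {no effects, shared placebo, shared placebo+test, individual
placebo + shared test, individual placebo + test}. A test effect without a
placebo effect is rejected as ill-formed, because test days always include
the placebo term.

### Diary expansion

Diaries record counts per day, not event times. A day with count `f`
places events at `(j/f)·24 h` from the start of the day (`j = 1..f`), so a
subject with exactly one movement per day yields 24-h intervals and a day
with three movements contributes three 8-h intervals. The span before the
first observed event is discarded (no left-censoring model: only observed
intervals are fitted). Zero-count days extend the interval that ends at the
next event. An interval is labelled with the condition of the day it
**ends** on — the hazard acting at the moment of the event; an interval
spanning a condition boundary therefore takes the end-day's label, an
arbitrary but documented rule for these rare intervals. Interval lengths are
kept as exact rationals internally so the zero-variance exclusion (all
intervals identical — e.g. exactly one movement a day for the whole trial)
is an exact comparison. Subjects with fewer than two events are likewise
excluded and reported.

### Sampling and diagnostics

Since no probabilistic-programming backend is part of the dependency set,
the sampler is implemented in the package: multinomial No-U-Turn HMC with
recursive doubling, sub-tree U-turn checks, dual-averaging step-size
adaptation (target acceptance 0.8) and a diagonal mass matrix estimated once
from the middle 25–80% of warm-up (regularised sample variances — a
single-window version of the usual staged scheme). Gradients of all three
likelihood families are analytic. Per-subject effects use a non-centred
parameterisation (`β = σ·z`, `z ~ N(0,1)`); `gut_state` and `log k` are
centred, which suits their comparatively informative per-subject data.
Positivity constraints are handled by log transforms with the Jacobian in
the target density. Exponent arguments are clipped (at 80) so that divergent
excursions produce finite gradients; the energy-error check (threshold 1000)
rejects those states.

Convergence is judged by the split-chain rank-normalised potential scale
reduction factor (R̂) per parameter, threshold 1.1; the implementation is
cross-checked against arviz in the test suite. `fit_model` refuses to report
(raises) when any R̂ exceeds the threshold unless `strict=False`, in which
case the condition is recorded as a warning on the result object.

The reference protocol is 20,000 iterations × 8 chains with 1,000 burn-in
per chain and no thinning. The package-default configuration for desk-scale
work is 4 chains × 2,000 iterations (1,000 burn-in), which reaches
R̂ ≤ 1.01 on simulated 10-subject cohorts; the full protocol remains
available via `MCMCConfig()`.

### WAIC and responder classification

WAIC is computed from the pointwise log-likelihood matrix (kept draws ×
observations) as `−2(lppd − p_waic)` with log-sum-exp-stabilised lppd and
the sample-variance (ddof = 1) penalty; a single draw defines `p_waic = 0`.
Model ranking requires identical observation sets and breaks ties toward the
simpler effect structure. Classification reads the posterior of
`β_{s,test}`: SR if the 2.5% quantile of the equal-tailed 95% credible
interval is positive, else WR if the posterior mean is positive, else NR.
(The alternative reading — a credible interval of a posterior-*predictive*
contrast rather than of the parameter — is not used; the parameter posterior
is the interpretation adopted throughout.)

## Feature statistics

* Shannon diversity in nats on renormalised proportions.
* Beta diversity `1 − ρ_Spearman` between sample rows (mid-rank ties);
  constant rows are rejected by name.
* Classical (Torgerson) MDS: double-centre `−D²/2`, top eigenpairs,
  eigenvector scaling by `√λ` with negative eigenvalues truncated, and each
  axis's sign fixed so its largest-magnitude loading is positive
  (deterministic output).
* Paired Wilcoxon signed-rank: zero differences dropped (p = 1 when none
  remain), exact null for n ≤ 25 without ties in |d|, tie-corrected normal
  approximation otherwise; Benjamini–Hochberg step-up q-values.
* Carry-over check: the original report does not name its test, so the
  package uses a two-sided Mann–Whitney comparison of arm-A vs arm-B
  within-subject beta-diversity distances — exact when untied, tie-corrected
  normal without continuity correction otherwise (so symmetric
  configurations give p = 1), consistent with the rank-based toolkit used
  everywhere else.
* Responder scores: `((T2−T1) − (C2−C1))/mean(C1,T1)` (1-week) and the T3
  analogue (2-week); a zero baseline mean gives NaN with a warning. Both
  horizons are exposed; the 1-week horizon is the default focus in the
  examples.
* Fold changes FCs = mean(SR)/mean(NR), FCw = mean(WR)/mean(NR) at baseline
  T1, arithmetic means; when a group mean is exactly zero, half the smallest
  positive value of the table is added to both numerator and denominator of
  that ratio (the mean type and zero handling are otherwise unspecified
  choices). FCs is undefined (NaN) when no SR exists; an empty NR or WR
  group is an error.
* Jonckheere–Terpstra: `J` counts concordant cross-group pairs with ties at
  one half. Exact p by full enumeration of group assignments for total
  n ≤ 12; seeded Monte-Carlo permutation (default 99,999 resamples, add-one
  correction) or tie-corrected normal approximation beyond. Two-sided
  p = 2·min(P(≥J), P(≤J)) capped at 1. Features pass the trend screen when
  `FCs > FCw > 1` or `FCs < FCw < 1` **and** raw p < 0.05 (no multiplicity
  correction at this step, by design).

## Responder prediction

Inputs are subject × feature baseline (T1) matrices per source (genus
relative abundance, metabolite content), the binary responder label
(SR ∪ WR vs NR) and the posterior-mean `β_{s,test}` as the continuous
selection target. Within every training fold, in order: features with
training-mean strictly above the source's threshold are kept; features are
z-scored with training means and population SDs (zero-SD features dropped);
LASSO (objective `(2n)⁻¹‖y − Xβ‖² + α‖β‖₁`) regressed on the effect means
selects the non-zero-coefficient features; an L2 logistic model (C = 1.0,
the customary default on standardised features) is fitted on the selected
features and scores the held-out fold. Standardising inside the folds (not
globally) avoids information leakage — the test suite asserts that
perturbing held-out rows cannot change a fitted fold model.

Evaluation: 7-fold stratified cross-validation, partitions resampled 10
times with seeded shuffling. Out-of-fold predictions of one partition are
pooled into a single AUROC (fold-wise AUROC is unstable with ~3-subject test
folds at cohort sizes around 20), then averaged over partitions; accuracy
and F-measure use threshold 0.5. The grid search covers genus thresholds
{0, 0.01}, metabolite thresholds {10, 100} and LASSO α {0.0001, 0.001} by
default (an absent source deactivates its threshold axis); ties in averaged
AUROC go to the sparser model (higher α, then higher thresholds). The whole
procedure is deterministic given the seed.

## Synthetic data

`simulate_trial` mirrors the generative side of the interval model: per
subject, parameters are drawn from the model's own priors (defaults
σ_k = 0.5, σ_gut_state = 0.5, σ_placebo = 0.3, σ_test = 0.5) unless given
explicitly, and events accumulate as a Weibull renewal process over the
two-arm design (defaults 14-day pre-observation, 14-day intervention,
28-day washout, 14-day intervention; arms alternate A/B). An interval is
drawn under the condition of the day it *starts*, while the analysis labels
it by end day — a deliberate mild mismatch mirroring real discretisation at
condition boundaries. Daily counts come from binning exact event times; the
day-fraction discretisation happens only on the analysis side. Because
shapes are drawn from the half-normal prior, some subjects legitimately
produce almost no events; the pipeline excludes them exactly as it excludes
degenerate clinical subjects, so simulated cohorts exercise that path too.

`simulate_feature_tables` builds latent log-abundances per feature as
feature mean + subject random effect + timepoint noise (within-subject
correlation 0.7 by default, in line with the observation that a person's
gut profile is far more similar to itself over time than to other people's).
Informative baseline features are shifted in proportion to the subject's
standardised true test effect; designated "SCFA-like" metabolites receive a
post-intervention (T2, T3) rise proportional to the effect. Genus tables are
closed to row sums of one (which induces realistic compositional
counter-movements in non-informative features); metabolite tables are
positive and unclosed.

What the simulators do **not** emulate: phylogenetic correlation structure,
diet covariates, missing diary days, sequencing depth noise, or
batch/measurement drift. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to those real-data complications.

## Problem sizes and test scale

The test suite runs the full pipeline at desk scale, chosen as the smallest
sizes at which the statistical claims are stable: convergence on a
10-subject, 70-day cohort at 4 chains × 2,000 iterations; a three-replicate
recovery smoke study (12 subjects, 2 chains × 1,200) checking rank
correlation between true and posterior-mean effects and pooled 95%
credible-interval coverage; WAIC selection across the five-variant family on
ten replicate cohorts at 2 chains × 600; and the cross-validated prediction
study on a 40-subject planted-signal cohort. Larger replication runs use the
same code paths with `MCMCConfig()` defaults.

## Known limitations

* Shared-effect variants use a fixed Normal(0, 1) prior for the scalar
  effect rather than a learned scale.
* The WAIC comparison is only defined within a response family; Weibull
  (interval) and Poisson/Bernoulli (daily) likelihoods are on different
  observation units and are deliberately not ranked against each other.
* The carry-over test statistic and several small numerical conventions
  (pseudocount, tie handling, exact-method cutoffs) are reasonable defaults
  for unspecified details, and are centralised so sensitivity analyses are
  easy.
* No time-varying covariates beyond the three-condition factor; no
  alternative survival families (log-normal, gamma); no left-censoring of
  the first interval.
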