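"""Simulate a crossover trial, fit the Weibull interval model, classify
responders.

Ten subjects follow the two-arm crossover design (14-day pre-observation,
14-day intervention, 28-day washout, 14-day intervention).  Each subject's
bowel movements come from a Weibull renewal process whose hazard rises by
exp(beta_test) on test-supplement days.  The hierarchical model recovers the
per-subject effects, and subjects are labelled SR (95% credible interval
above zero), WR (posterior mean above zero) or NR.
"""

import pandas as pd

from gutresponder import (
    MCMCConfig,
    ModelSpec,
    TrialSimConfig,
    classify_responders,
    fit_model,
    simulate_trial,
)
from gutresponder.diary import prepare_interval_series

trial = simulate_trial(TrialSimConfig(n_subjects=10, seed=42))
series, excluded = prepare_interval_series(trial.diaries)
print(f"{len(series)} fittable subjects; excluded (too few events or "
      f"zero interval variance): {excluded or 'none'}")

fit = fit_model(
    series,
    ModelSpec("weibull_interval", "individual", "individual"),
    MCMCConfig(iterations=2000, chains=4, burn_in=1000, seed=0),
    strict=False,
)
print(f"max split-chain Rhat = {fit.max_rhat:.4f} "
      f"(convergence requires <= 1.1)\n")

calls = classify_responders(fit, excluded=excluded)
truth = trial.true_params.set_index("subject_id")["beta_test"]
rows = [
    {
        "subject": c.subject_id,
        "label": c.label,
        "posterior_mean": round(c.beta_test_mean, 3),
        "ci_2.5%": round(c.ci_low, 3),
        "ci_97.5%": round(c.ci_high, 3),
        "true_beta_test": round(float(truth.get(c.subject_id, float("nan"))),
                                3),
    }
    for c in calls
]
print(pd.DataFrame(rows).to_string(index=False))
print("\nA positive beta_test means the test supplement shortens this "
      "subject's bowel-movement intervals (more frequent movements); the "
      "label compares the posterior of beta_test with zero.")
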