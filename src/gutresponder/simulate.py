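"""Synthetic crossover trials: Weibull renewal diaries and feature tables.

``simulate_trial`` mirrors the generative side of the interval model: each
subject's bowel movements form a renewal process whose Weibull hazard is
modulated by the condition (baseline / placebo / test) in force on the day an
interval starts.  Event times are binned into daily counts, producing exactly
the diary format the analysis pipeline ingests, together with the generating
parameters for recovery tests.

``simulate_feature_tables`` produces compositional genus tables and positive
metabolite tables at the six sampling timepoints (C1-C3, T1-T3) with planted
responder structure: designated baseline features shift with the subject's
true test effect, and designated "SCFA-like" metabolites rise after the test
intervention in proportion to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diary import DefecationDiary, DiaryDay, StudyDesign
from .features import FeatureTable

__all__ = [
    "TrialSimConfig",
    "FeatureSimConfig",
    "TrialSimResult",
    "simulate_trial",
    "simulate_feature_tables",
    "default_design",
]

_MAX_EVENTS_PER_SUBJECT = 100_000


def default_design(arm: str = "A") -> StudyDesign:
    """The default two-arm crossover layout: 14 days pre-observation,
    14-day intervention, 28-day washout, 14-day intervention (70 days).

    Sampling timepoints sit at the start and ends of the intervention weeks:
    x1 just before a period starts, x2 after one week, x3 after two weeks
    (x = T for the test period, C for the control period)."""
    pre = (0, 14)
    i1 = (14, 28)
    wash = (28, 56)
    i2 = (56, 70)
    first, second = ("T", "C") if arm == "A" else ("C", "T")
    timepoints = {
        f"{first}1": i1[0], f"{first}2": i1[0] + 7, f"{first}3": i1[1] - 1,
        f"{second}1": i2[0], f"{second}2": i2[0] + 7, f"{second}3": i2[1] - 1,
    }
    return StudyDesign(arm=arm, pre=pre, intervention1=i1, washout=wash,
                       intervention2=i2, timepoints=timepoints)


@dataclass(frozen=True)
class TrialSimConfig:
    """Conditions of the simulated crossover trial.

    Per-subject parameters are drawn from the model's own priors —
    ``k ~ HalfNormal(0, sigma_k)``, ``gut_state ~ Normal(0, sigma_gut_state)``
    and likewise for the two effects — unless explicit values are supplied.
    Defaults match the hierarchical scales used throughout the recovery
    studies.  Period lengths are days; arm assignment alternates A/B unless
    a rule is given.
    """

    n_subjects: int = 10
    period_lengths: tuple[int, int, int, int] = (14, 14, 28, 14)
    sigma_k: float = 0.5
    sigma_gut_state: float = 0.5
    sigma_placebo: float = 0.3
    sigma_test: float = 0.5
    k: Sequence[float] | None = None
    gut_state: Sequence[float] | None = None
    beta_placebo: Sequence[float] | None = None
    beta_test: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(p < 1 for p in self.period_lengths):
            raise ValueError("period lengths must be >= 1 day")
        for name in ("sigma_k", "sigma_gut_state", "sigma_placebo",
                     "sigma_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k", "gut_state", "beta_placebo", "beta_test"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_subjects:
                raise ValueError(f"{name} must have length n_subjects")


@dataclass
class TrialSimResult:
    diaries: list[DefecationDiary]
    designs: dict[str, StudyDesign]
    true_params: pd.DataFrame  # subject_id, arm, k, gut_state, betas

    def truth(self, column: str) -> np.ndarray:
        return self.true_params[column].to_numpy()


def _design_from_lengths(lengths: tuple[int, int, int, int],
                         arm: str) -> StudyDesign:
    p, i1, w, i2 = lengths
    b0, b1, b2, b3, b4 = 0, p, p + i1, p + i1 + w, p + i1 + w + i2
    first, second = ("T", "C") if arm == "A" else ("C", "T")
    timepoints = {
        f"{first}1": b1, f"{first}2": min(b1 + 7, b2 - 1), f"{first}3": b2 - 1,
        f"{second}1": b3, f"{second}2": min(b3 + 7, b4 - 1),
        f"{second}3": b4 - 1,
    }
    return StudyDesign(arm=arm, pre=(b0, b1), intervention1=(b1, b2),
                       washout=(b2, b3), intervention2=(b3, b4),
                       timepoints=timepoints)


def simulate_trial(config: TrialSimConfig) -> TrialSimResult:
    """Simulate condition-dependent Weibull renewal diaries.

    Each interval is drawn under the condition in force on the day it starts
    (the analysis path labels intervals by the day they end; the mild
    mismatch at condition boundaries mirrors real discretisation).  Interval
    sampling uses the rate parameterisation: ``t = (E / lambda)^(1/k)`` with
    ``E ~ Exponential(1)`` and ``lambda = exp(eta)``.
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_subjects

    def draw_or_given(given, sampler):
        return (np.asarray(given, float) if given is not None
                else sampler(size=S))

    k = draw_or_given(config.k,
                      lambda size: np.abs(rng.normal(0, config.sigma_k, size)))
    k = np.maximum(k, 1e-6)
    gut = draw_or_given(config.gut_state,
                        lambda size: rng.normal(0, config.sigma_gut_state,
                                                size))
    bp = draw_or_given(config.beta_placebo,
                       lambda size: rng.normal(0, config.sigma_placebo, size))
    bt = draw_or_given(config.beta_test,
                       lambda size: rng.normal(0, config.sigma_test, size))

    horizon = sum(config.period_lengths)
    diaries, rows = [], []
    designs: dict[str, StudyDesign] = {}
    for s in range(S):
        arm = "A" if s % 2 == 0 else "B"
        design = _design_from_lengths(config.period_lengths, arm)
        sid = f"S{s + 1:02d}"
        designs[sid] = design
        conditions = [design.condition_of_day(d) for d in range(horizon)]
        eta_by_cond = {
            "baseline": gut[s],
            "placebo": gut[s] + bp[s],
            "test": gut[s] + bp[s] + bt[s],
        }
        t = 0.0
        counts = np.zeros(horizon, dtype=int)
        n_events = 0
        while True:
            day = min(int(t), horizon - 1)
            lam = np.exp(eta_by_cond[conditions[day]])
            with np.errstate(over="ignore"):
                # tiny shapes give astronomically heavy tails; an overflowing
                # draw is simply an interval beyond the trial horizon
                interval = (rng.exponential() / lam) ** (1.0 / k[s])
            t += interval
            if t >= horizon:
                break
            counts[int(t)] += 1
            n_events += 1
            if n_events > _MAX_EVENTS_PER_SUBJECT:
                raise RuntimeError(
                    f"subject {sid}: event cap exceeded (k={k[s]:.3g}, "
                    f"gut_state={gut[s]:.3g}); implausible configuration"
                )
        days = tuple(
            DiaryDay(d, int(counts[d]), conditions[d]) for d in range(horizon)
        )
        diaries.append(DefecationDiary(subject_id=sid, days=days))
        rows.append({"subject_id": sid, "arm": arm, "k": k[s],
                     "gut_state": gut[s], "beta_placebo": bp[s],
                     "beta_test": bt[s], "n_events": n_events})

    return TrialSimResult(diaries=diaries, designs=designs,
                         true_params=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Feature tables with planted responder structure


@dataclass(frozen=True)
class FeatureSimConfig:
    """Conditions of the synthetic metabologenomic tables.

    ``baseline_effect`` scales how strongly the informative baseline features
    track the subject's true test effect (log scale); ``scfa_shift`` scales
    the post-intervention (T2, T3) rise of the SCFA-like metabolites in
    responders.  ``timepoint_rho`` is the within-subject correlation of a
    feature across timepoints.
    """

    n_genera: int = 50
    n_metabolites: int = 50
    n_informative_genera: int = 5
    n_informative_metabolites: int = 5
    n_scfa_like: int = 2
    baseline_effect: float = 1.0
    scfa_shift: float = 1.0
    timepoint_rho: float = 0.7
    noise_scale: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_genera > self.n_genera:
            raise ValueError("n_informative_genera > n_genera")
        if (self.n_informative_metabolites + self.n_scfa_like
                > self.n_metabolites):
            raise ValueError("informative + SCFA-like exceeds n_metabolites")
        if not 0 <= self.timepoint_rho < 1:
            raise ValueError("timepoint_rho must be in [0, 1)")


TIMEPOINTS = ("C1", "C2", "C3", "T1", "T2", "T3")


def simulate_feature_tables(
    config: FeatureSimConfig,
    subject_ids: Sequence[str],
    beta_test: Sequence[float],
) -> tuple[FeatureTable, FeatureTable, dict[str, list[str]]]:
    """Genus and metabolite tables at C1-C3 / T1-T3 with planted signal.

    Returns ``(genus_table, metabolite_table, truth)`` where ``truth`` lists
    the informative genus / metabolite / SCFA-like feature names.  Latent
    log-abundances decompose into a feature-level mean, a subject-level
    random effect (within-subject correlation across timepoints) and
    timepoint noise; the genus table is closed to row sums of one.
    """
    rng = np.random.default_rng(config.seed)
    bt = np.asarray(beta_test, float)
    if len(subject_ids) != bt.size:
        raise ValueError("subject_ids and beta_test lengths differ")
    bt_std = (bt - bt.mean()) / (bt.std() if bt.std() > 0 else 1.0)

    def latent(n_features, n_informative, planted_rows_scale):
        """(subjects, timepoints, features) latent log-abundances."""
        S, T = len(subject_ids), len(TIMEPOINTS)
        mu = rng.normal(0.0, 1.0, size=n_features)
        tau = config.noise_scale * np.sqrt(config.timepoint_rho)
        omega = config.noise_scale * np.sqrt(1 - config.timepoint_rho)
        subject_eff = rng.normal(0.0, tau, size=(S, 1, n_features))
        noise = rng.normal(0.0, omega, size=(S, T, n_features))
        x = mu[None, None, :] + subject_eff + noise
        inf_idx = np.arange(n_informative)
        x[:, :, inf_idx] += (planted_rows_scale
                             * bt_std[:, None, None]
                             * np.ones((1, 1, n_informative)))
        return x, inf_idx

    xg, g_inf = latent(config.n_genera, config.n_informative_genera,
                       config.baseline_effect)
    genus_names = [f"g__Genus{j + 1:03d}" for j in range(config.n_genera)]

    xm, m_inf = latent(config.n_metabolites, config.n_informative_metabolites,
                       config.baseline_effect)
    met_names = [f"met{j + 1:03d}" for j in range(config.n_metabolites)]
    # SCFA-like metabolites: post-intervention rise in responders at T2, T3
    scfa_idx = np.arange(config.n_metabolites - config.n_scfa_like,
                         config.n_metabolites)
    for tp_i, tp in enumerate(TIMEPOINTS):
        if tp in ("T2", "T3"):
            xm[:, tp_i, scfa_idx] += config.scfa_shift * bt_std[:, None]

    index = pd.MultiIndex.from_tuples(
        [(sid, tp) for sid in subject_ids for tp in TIMEPOINTS],
        names=["subject_id", "timepoint"],
    )
    S, T = len(subject_ids), len(TIMEPOINTS)

    genus_vals = np.exp(xg).reshape(S * T, config.n_genera)
    genus_vals = genus_vals / genus_vals.sum(axis=1, keepdims=True)
    genus = FeatureTable(
        pd.DataFrame(genus_vals, index=index, columns=genus_names),
        kind="genus_relab",
    )
    met_vals = 100.0 * np.exp(xm).reshape(S * T, config.n_metabolites)
    metab = FeatureTable(
        pd.DataFrame(met_vals, index=index, columns=met_names),
        kind="metabolite_content",
    )
    truth = {
        "informative_genera": [genus_names[j] for j in g_inf],
        "informative_metabolites": [met_names[j] for j in m_inf],
        "scfa_like": [met_names[j] for j in scfa_idx],
    }
    return genus, metab, truth
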