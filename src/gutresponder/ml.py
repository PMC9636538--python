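"""Responder prediction from baseline metabologenomic features.

The pipeline mirrors how responders are predicted from pre-intervention
(T1) data: per-source abundance filtering, z-scoring, LASSO feature
selection regressed on the posterior-mean individual supplement effect,
then an L2 logistic classifier of responder (SR or WR) versus NR, evaluated
by repeated stratified cross-validation with a grid search over thresholds
and the LASSO penalty.  All data-dependent steps (filter, z-score, LASSO)
are fitted inside the training folds only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MLGrid",
    "CVResult",
    "filter_by_abundance",
    "zscore_fit_apply",
    "lasso_select",
    "logistic_train_predict",
    "auroc",
    "f_measure",
    "cross_validated_grid_search",
]


@dataclass(frozen=True)
class MLGrid:
    """Grid-search space.  Defaults are the canonical grid: genus
    relative-abundance thresholds {0, 0.01}, metabolite content thresholds
    {10, 100}, LASSO penalties {0.0001, 0.001}."""

    genus_thresholds: tuple[float, ...] = (0.0, 0.01)
    metabolite_thresholds: tuple[float, ...] = (10.0, 100.0)
    alphas: tuple[float, ...] = (0.0001, 0.001)

    def __post_init__(self) -> None:
        if not self.alphas:
            raise ValueError("at least one alpha is required")
        if any(a <= 0 for a in self.alphas):
            raise ValueError("alphas must be > 0")
        if any(t < 0 for t in
               self.genus_thresholds + self.metabolite_thresholds):
            raise ValueError("thresholds must be >= 0")

    def points(self, sources: Sequence[str]) -> list[dict]:
        """Grid points restricted to the supplied data sources; an absent
        table deactivates its threshold axis."""
        axes = []
        if "genus" in sources:
            axes.append([("genus_threshold", t)
                         for t in self.genus_thresholds])
        if "metabolite" in sources:
            axes.append([("metabolite_threshold", t)
                         for t in self.metabolite_thresholds])
        axes.append([("alpha", a) for a in self.alphas])
        return [dict(combo) for combo in itertools.product(*axes)]


def filter_by_abundance(
    table: pd.DataFrame, threshold: float,
    train_index: Sequence | None = None,
) -> pd.DataFrame:
    """Keep features whose mean value over the (training) samples is
    strictly above ``threshold``.

    With ``train_index`` given, means are computed on those rows only but
    the full table is returned with the reduced feature set, so the same
    selection applies to held-out samples without looking at them.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ref = table if train_index is None else table.loc[train_index]
    means = ref.mean(axis=0)
    kept = means.index[means > threshold]
    if len(kept) == 0:
        raise ValueError(
            f"threshold {threshold} removes every feature "
            f"(max feature mean {means.max():.4g}); lower the threshold"
        )
    return table[kept]


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Standardise features to zero mean / unit SD using training statistics.

    The per-feature mean and population SD (denominator n) come from the
    training rows only and are applied to both matrices; features with zero
    training SD are dropped from both (with a warning).
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} zero-variance feature(s) before "
            "z-scoring",
            UserWarning,
            stacklevel=2,
        )
    train_z = (train.loc[:, keep] - mean[keep]) / sd[keep]
    test_z = None
    if test is not None:
        test_z = (test.loc[:, keep] - mean[keep]) / sd[keep]
    return train_z, test_z


def lasso_select(
    X_train: pd.DataFrame, y_effect: np.ndarray, alpha: float
) -> list[str]:
    """Features with non-zero LASSO coefficients when regressing the
    posterior-mean individual supplement effect on the (standardised)
    training features; objective (1/2n)||y - Xb||^2 + alpha ||b||_1."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=100_000,
                  tol=1e-10)
    with warnings.catch_warnings():
        # tiny grid alphas on correlated compositional features rarely reach
        # the strict duality gap; the coefficients are stable regardless
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X_train.to_numpy(), np.asarray(y_effect, dtype=float))
    coef = model.coef_
    return [f for f, c in zip(X_train.columns, coef) if abs(c) > 1e-10]


def logistic_train_predict(
    X_train: pd.DataFrame,
    labels_train: np.ndarray,
    X_test: pd.DataFrame,
    C: float = 1.0,
) -> np.ndarray:
    """Responder probabilities for the test rows from an L2-regularised
    logistic model fitted on the training rows.

    An empty feature set yields the intercept-only model (training base
    rate); a single-class training set is the caller's error.
    """
    y = np.asarray(labels_train, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if X_train.shape[1] == 0:
        base = float(y.mean())
        return np.full(len(X_test), base)
    model = LogisticRegression(C=C, solver="lbfgs", tol=1e-10,
                               max_iter=10_000)
    model.fit(X_train.to_numpy(), y)
    return model.predict_proba(X_test.to_numpy())[:, 1]


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve: the Mann-Whitney statistic normalised by
    the number of positive-negative pairs, tied scores counted one half.
    Returns NaN when one class is absent."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def f_measure(predicted: Sequence[int], labels: Sequence[int]) -> float:
    """Harmonic mean of precision and recall for the responder class."""
    pred = np.asarray(predicted, dtype=int)
    y = np.asarray(labels, dtype=int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


@dataclass
class CVResult:
    """Metrics of one grid point over repeated stratified partitions."""

    grid_point: dict
    partition_auroc: list[float] = field(default_factory=list)
    partition_accuracy: list[float] = field(default_factory=list)
    partition_f_measure: list[float] = field(default_factory=list)
    selected_features: list[list[str]] = field(default_factory=list)
    skipped_folds: int = 0
    seed: int = 0

    @property
    def mean_auroc(self) -> float:
        vals = [v for v in self.partition_auroc if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.partition_accuracy))

    @property
    def mean_f_measure(self) -> float:
        return float(np.mean(self.partition_f_measure))


def _fit_fold(
    tables: Mapping[str, pd.DataFrame],
    point: dict,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    y_effect: np.ndarray,
    labels: np.ndarray,
):
    """One fold: per-source filter -> joint z-score -> LASSO -> logistic."""
    subjects = next(iter(tables.values())).index
    train_subj = subjects[train_idx]
    blocks_train, blocks_test = [], []
    for source, table in tables.items():
        thr = point.get(f"{source}_threshold", 0.0)
        filtered = filter_by_abundance(table, thr, train_index=train_subj)
        blocks_train.append(filtered.iloc[train_idx])
        blocks_test.append(filtered.iloc[test_idx])
    X_train = pd.concat(blocks_train, axis=1)
    X_test = pd.concat(blocks_test, axis=1)
    X_train, X_test = zscore_fit_apply(X_train, X_test)
    selected = lasso_select(X_train, y_effect[train_idx], point["alpha"])
    probs = logistic_train_predict(
        X_train[selected], labels[train_idx], X_test[selected]
    )
    return probs, selected


def cross_validated_grid_search(
    tables: Mapping[str, pd.DataFrame],
    labels: np.ndarray,
    y_effect: np.ndarray,
    grid: MLGrid = MLGrid(),
    k: int = 7,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[dict, list[CVResult]]:
    """Grid search over thresholds and LASSO penalty with repeated
    stratified cross-validation.

    ``tables`` maps source name ("genus", "metabolite") to a subject x
    feature matrix at baseline; ``labels`` is the binary responder vector
    (1 = SR or WR, 0 = NR) and ``y_effect`` the per-subject posterior mean of
    the individual supplement effect, both aligned with the table rows.  For
    each grid point, ``repeats`` seeded stratified k-fold partitions are
    drawn; within each training fold the filter, z-scoring, and LASSO
    selection are re-fitted, the out-of-fold predictions of one partition
    are pooled into a single AUROC, and partitions are averaged.  The best
    grid point maximises the averaged AUROC, ties going to the sparser
    model (higher alpha, then higher thresholds).

    Returns ``(best_grid_point, [CVResult per grid point])``.
    """
    labels = np.asarray(labels, dtype=int)
    y_effect = np.asarray(y_effect, dtype=float)
    n = labels.size
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("stratification impossible: a class has < 2 samples")
    index_ref = None
    for name, t in tables.items():
        if len(t) != n:
            raise ValueError(f"table {name!r} has {len(t)} rows, expected {n}")
        if index_ref is None:
            index_ref = list(t.index)
        elif list(t.index) != index_ref:
            raise ValueError("tables must share the same subject order")

    results = []
    for point in grid.points(list(tables.keys())):
        res = CVResult(grid_point=point, seed=seed)
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=seed + r)
            pooled_scores = np.full(n, np.nan)
            for train_idx, test_idx in skf.split(np.zeros(n), labels):
                if np.unique(labels[train_idx]).size < 2:
                    res.skipped_folds += 1
                    continue
                probs, selected = _fit_fold(
                    tables, point, train_idx, test_idx, y_effect, labels
                )
                pooled_scores[test_idx] = probs
                res.selected_features.append(sorted(selected))
            mask = np.isfinite(pooled_scores)
            res.partition_auroc.append(
                auroc(pooled_scores[mask], labels[mask])
            )
            pred = (pooled_scores[mask] >= 0.5).astype(int)
            res.partition_accuracy.append(
                float(np.mean(pred == labels[mask]))
            )
            res.partition_f_measure.append(
                f_measure(pred, labels[mask])
            )
        results.append(res)

    def sort_key(r: CVResult):
        p = r.grid_point
        return (
            -(r.mean_auroc if np.isfinite(r.mean_auroc) else -np.inf),
            -p["alpha"],
            -p.get("genus_threshold", 0.0),
            -p.get("metabolite_threshold", 0.0),
        )

    best = min(results, key=sort_key)
    return best.grid_point, results
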