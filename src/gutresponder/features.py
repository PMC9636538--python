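"""Descriptive and responder-feature statistics on metabologenomic tables.

Covers alpha diversity (Shannon index), Spearman-correlation beta diversity
with classical multidimensional scaling, paired Wilcoxon signed-rank tests
with Benjamini-Hochberg correction, the crossover carry-over check,
within-subject responder scores, SR/WR-vs-NR fold changes, and the
Jonckheere-Terpstra trend test across ordered responder groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "TrendResult",
    "shannon_index",
    "spearman_distance_matrix",
    "classical_mds",
    "paired_wilcoxon_bh",
    "carryover_check",
    "responder_score",
    "fold_changes",
    "jonckheere_terpstra",
    "select_trend_features",
]

TIMEPOINT_LABELS = ("C1", "C2", "C3", "T1", "T2", "T3")


class FeatureTable:
    """Sample x feature matrix keyed by (subject_id, timepoint).

    ``kind`` is ``"genus_relab"`` (rows must sum to one; rows off by more
    than 1e-6 are renormalised with a warning) or ``"metabolite_content"``
    (non-negative values).  The underlying data is a pandas DataFrame with a
    (subject_id, timepoint) MultiIndex.
    """

    KINDS = ("genus_relab", "metabolite_content")

    def __init__(self, values: pd.DataFrame, kind: str):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        if not isinstance(values.index, pd.MultiIndex):
            raise ValueError(
                "values must be indexed by a (subject_id, timepoint) "
                "MultiIndex"
            )
        bad_tp = set(values.index.get_level_values(1)) - set(TIMEPOINT_LABELS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError(f"{kind} values must be non-negative")
        if kind == "genus_relab":
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                warnings.warn(
                    "genus relative abundances do not sum to 1; renormalising",
                    UserWarning,
                    stacklevel=2,
                )
                values = values.div(sums, axis=0)
        self.values = values
        self.kind = kind

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.values.index.get_level_values(0)))

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        """Subject x feature matrix at one sampling timepoint."""
        sub = self.values.xs(timepoint, level=1)
        return sub

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index = [f"{s}:{t}" for s, t in out.index]
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = [tuple(k.split(":", 1)) for k in df.index]
        df.index = pd.MultiIndex.from_tuples(
            pairs, names=["subject_id", "timepoint"]
        )
        return cls(df, kind)


# ---------------------------------------------------------------------------
# Diversity and ordination


def shannon_index(abundances: Sequence[float]) -> float:
    """Shannon diversity in nats: -sum p ln p over positive proportions."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one positive abundance is required")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def spearman_distance_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distances 1 - Spearman rho (mid-rank ties)."""
    df = table.values if isinstance(table, FeatureTable) else table
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 3:
        raise ValueError("need >= 2 samples and >= 3 features")
    const = np.all(arr == arr[:, :1], axis=1)
    if const.any():
        bad = [str(df.index[i]) for i in np.where(const)[0]]
        raise ValueError(
            f"constant sample row(s) {bad}: Spearman correlation undefined"
        )
    rho = ss.spearmanr(arr, axis=1).statistic
    if arr.shape[0] == 2:  # scipy returns a scalar for two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=df.index, columns=df.index)


def classical_mds(distances: pd.DataFrame | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres -D^2/2, takes the top ``dims`` eigenpairs, scales
    eigenvectors by the square root of their (non-negative) eigenvalues, and
    fixes each axis's sign so that its largest-magnitude loading is positive.
    """
    D = (distances.to_numpy(dtype=float)
         if isinstance(distances, pd.DataFrame) else
         np.asarray(distances, dtype=float))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


# ---------------------------------------------------------------------------
# Paired tests, FDR, carry-over


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided signed-rank p: zeros dropped, exact null for n <= 25 with
    untied absolute differences, tie-corrected normal approximation
    otherwise; 1.0 when no informative pairs remain."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    absd = np.abs(d)
    has_ties = np.unique(absd).size < absd.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    return float(ss.wilcoxon(d, method=method).pvalue)


def paired_wilcoxon_bh(
    table_x: pd.DataFrame, table_y: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature paired Wilcoxon signed-rank p-values with BH q-values.

    Rows of the two tables must be the same subjects (e.g. values at C2 vs
    T2); columns are features.  Returns a DataFrame with columns ``p`` and
    ``q`` indexed by feature.
    """
    if list(table_x.index) != list(table_y.index):
        raise ValueError("tables must be matched on the same subjects")
    if list(table_x.columns) != list(table_y.columns):
        raise ValueError("tables must share the same features")
    ps = np.array(
        [
            _wilcoxon_p(table_x[c].to_numpy(), table_y[c].to_numpy())
            for c in table_x.columns
        ]
    )
    q = multipletests(ps, method="fdr_bh")[1]
    return pd.DataFrame({"p": ps, "q": q}, index=table_x.columns)


def carryover_check(
    within_subject_distance: Mapping[str, float], arm: Mapping[str, str]
) -> tuple[float, float]:
    """Crossover carry-over check: compare arm-A vs arm-B within-subject
    distances (each subject's beta-diversity distance between its two
    intervention-period samples) with a two-sided Mann-Whitney rank-sum test.

    Returns ``(U statistic, p)``.  A large p supports the absence of a
    carry-over effect.
    """
    a = [within_subject_distance[s] for s in within_subject_distance
         if arm[s] == "A"]
    b = [within_subject_distance[s] for s in within_subject_distance
         if arm[s] == "B"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least 2 subjects")
    pooled = np.array(a + b)
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties:
        # tie-corrected normal approximation without continuity correction,
        # so that perfectly symmetric configurations give p = 1
        res = ss.mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic", use_continuity=False)
    else:
        res = ss.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Responder scores, fold changes, trend testing


def responder_score(
    c1: float, c2: float, c3: float, t1: float, t2: float, t3: float,
    horizon: str = "1wk",
) -> float:
    """Within-subject intervention contrast normalised by baseline level.

    1-week score: ((T2 - T1) - (C2 - C1)) / mean(C1, T1);
    2-week score: ((T3 - T1) - (C3 - C1)) / mean(C1, T1).
    Returns NaN (with a warning) when the baseline mean is zero.
    """
    base = 0.5 * (c1 + t1)
    if base == 0:
        warnings.warn("zero baseline mean; responder score undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    if horizon == "1wk":
        return ((t2 - t1) - (c2 - c1)) / base
    if horizon == "2wk":
        return ((t3 - t1) - (c3 - c1)) / base
    raise ValueError(f"horizon must be '1wk' or '2wk', got {horizon!r}")


def fold_changes(
    values_at_t1: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """FCs and FCw per feature: group-mean ratios SR/NR and WR/NR at
    baseline timepoint T1.

    ``values_at_t1`` is subject x feature; ``labels`` maps subject to
    SR/WR/NR (other labels ignored).  When a group mean is exactly zero a
    pseudocount of half the smallest positive value in the table is added to
    both numerator and denominator of that ratio.  FCs is NaN when no SR
    subjects exist; an empty NR group is an error.
    """
    groups = {g: [s for s in values_at_t1.index if labels.get(s) == g]
              for g in ("SR", "WR", "NR")}
    if not groups["NR"]:
        raise ValueError("NR group is empty; fold changes are undefined")
    if not groups["WR"]:
        raise ValueError("WR group is empty; fold changes are undefined")
    arr = values_at_t1.to_numpy(dtype=float)
    pos = arr[arr > 0]
    eps = 0.5 * pos.min() if pos.size else 0.5

    def ratio(g: str) -> np.ndarray:
        if not groups[g]:
            return np.full(values_at_t1.shape[1], np.nan)
        num = values_at_t1.loc[groups[g]].mean(axis=0).to_numpy()
        den = values_at_t1.loc[groups["NR"]].mean(axis=0).to_numpy()
        zero = (num == 0) | (den == 0)
        num = np.where(zero, num + eps, num)
        den = np.where(zero, den + eps, den)
        return num / den

    return pd.DataFrame(
        {"FCs": ratio("SR"), "FCw": ratio("WR")}, index=values_at_t1.columns
    )


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """J = sum over ordered pairs of groups of cross-pair concordances,
    ties counted one half."""
    j = 0.0
    for gi, gh in itertools.combinations(range(len(groups)), 2):
        x, y = groups[gi], groups[gh]
        less = (x[:, None] < y[None, :]).sum()
        equal = (x[:, None] == y[None, :]).sum()
        j += less + 0.5 * equal
    return float(j)


def _jt_null_exact(pooled: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Full enumeration of J over all assignments of the pooled values to
    the given group sizes."""
    n = pooled.size
    stats = []
    idx_all = list(range(n))

    def rec(remaining: list[int], sizes_left: Sequence[int],
            chosen: list[np.ndarray]):
        if len(sizes_left) == 1:
            groups = chosen + [pooled[np.array(remaining)]]
            stats.append(_jt_statistic(groups))
            return
        for comb in itertools.combinations(range(len(remaining)),
                                           sizes_left[0]):
            comb_set = set(comb)
            grp = pooled[np.array([remaining[i] for i in comb])]
            rest = [remaining[i] for i in range(len(remaining))
                    if i not in comb_set]
            rec(rest, sizes_left[1:], chosen + [grp])

    rec(idx_all, list(sizes), [])
    return np.asarray(stats)


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    two_sided: bool = True,
    method: str = "auto",
    n_permutations: int = 99_999,
    seed: int = 0,
) -> tuple[float, float]:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups
    (e.g. NR < WR < SR).

    ``J`` counts, over every ordered pair of groups, the pairs of
    observations that agree with the ordering (ties contribute one half).
    ``method`` is ``"exact"`` (full enumeration), ``"permutation"``
    (seeded Monte-Carlo), ``"asymptotic"`` (tie-corrected normal
    approximation) or ``"auto"`` (exact when total n <= 12, else
    asymptotic).  The two-sided p is ``2 * min(P(>= J), P(<= J))`` capped at
    one.  Returns ``(J, p)``.
    """
    gs = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(gs) < 2:
        raise ValueError("need at least two non-empty ordered groups")
    n_total = sum(g.size for g in gs)
    j_obs = _jt_statistic(gs)
    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]

    if method == "auto":
        method = "exact" if n_total <= 12 else "asymptotic"

    if method == "exact":
        null = _jt_null_exact(pooled, sizes)
        tol = 1e-9
        p_ge = np.mean(null >= j_obs - tol)
        p_le = np.mean(null <= j_obs + tol)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        ge = le = 0
        tol = 1e-9
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            jj = _jt_statistic(parts)
            ge += jj >= j_obs - tol
            le += jj <= j_obs + tol
        p_ge = (1 + ge) / (1 + n_permutations)
        p_le = (1 + le) / (1 + n_permutations)
    elif method == "asymptotic":
        # mean and tie-corrected variance of J under the null
        n = n_total
        counts = pd.Series(pooled).value_counts().to_numpy()
        mean_j = (n * n - sum(m * m for m in sizes)) / 4.0
        t1 = n * (n - 1) * (2 * n + 5)
        t1 -= sum(m * (m - 1) * (2 * m + 5) for m in sizes)
        t1 -= sum(t * (t - 1) * (2 * t + 5) for t in counts)
        t2 = (sum(m * (m - 1) * (m - 2) for m in sizes)
              * sum(t * (t - 1) * (t - 2) for t in counts))
        t3 = (sum(m * (m - 1) for m in sizes)
              * sum(t * (t - 1) for t in counts))
        var_j = (t1 / 72.0
                 + t2 / (36.0 * n * (n - 1) * (n - 2))
                 + t3 / (8.0 * n * (n - 1)))
        if var_j <= 0:
            return j_obs, 1.0
        z = (j_obs - mean_j) / math.sqrt(var_j)
        p_ge = ss.norm.sf(z)
        p_le = ss.norm.cdf(z)
    else:
        raise ValueError(f"unknown method {method!r}")

    if two_sided:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        p = min(1.0, float(p_ge))
    return j_obs, float(p)


@dataclass(frozen=True)
class TrendResult:
    """A feature passing the fold-change ordering rule with its trend test."""

    feature: str
    fcs: float
    fcw: float
    j_statistic: float
    p: float
    direction: str  # increasing / decreasing


def select_trend_features(
    fold_change_table: pd.DataFrame,
    jt_results: Mapping[str, tuple[float, float]],
    alpha: float = 0.05,
) -> list[TrendResult]:
    """Features whose fold changes are ordered FCs > FCw > 1 (increasing) or
    FCs < FCw < 1 (decreasing) and whose Jonckheere-Terpstra p is below
    ``alpha`` (raw, uncorrected).
    """
    out = []
    for feature, row in fold_change_table.iterrows():
        fcs, fcw = row["FCs"], row["FCw"]
        if feature not in jt_results:
            continue
        if not (np.isfinite(fcs) and np.isfinite(fcw)):
            continue
        if fcs > fcw > 1:
            direction = "increasing"
        elif fcs < fcw < 1:
            direction = "decreasing"
        else:
            continue
        j, p = jt_results[feature]
        if p < alpha:
            out.append(TrendResult(str(feature), float(fcs), float(fcw),
                                   float(j), float(p), direction))
    return out
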