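"""Diversity, ordination, paired tests, fold changes and trend testing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given
from hypothesis import strategies as st

from gutresponder.features import (
    FeatureTable,
    carryover_check,
    classical_mds,
    fold_changes,
    jonckheere_terpstra,
    paired_wilcoxon_bh,
    responder_score,
    select_trend_features,
    shannon_index,
    spearman_distance_matrix,
)


def table_from(values, subjects, timepoint="T1", kind="metabolite_content"):
    idx = pd.MultiIndex.from_tuples([(s, timepoint) for s in subjects],
                                    names=["subject_id", "timepoint"])
    cols = [f"f{i}" for i in range(np.asarray(values).shape[1])]
    return FeatureTable(pd.DataFrame(values, index=idx, columns=cols), kind)


class TestShannon:
    def test_single_species_zero_diversity(self):
        assert shannon_index([1, 0, 0]) == 0.0

    def test_uniform_is_log_richness(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4))

    def test_hand_computed_mixture(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(
            -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=12))
    def test_permutation_invariant_and_bounded_by_uniform(self, vals):
        h = shannon_index(vals)
        assert h == pytest.approx(shannon_index(vals[::-1]))
        assert h <= math.log(len(vals)) + 1e-9


class TestSpearmanDistance:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        d = spearman_distance_matrix(df)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        assert spearman_distance_matrix(df).loc["a", "b"] == pytest.approx(2.0)

    def test_midrank_hand_oracle(self):
        """Three samples with ties: distances equal 1 - rho computed from
        hand-assigned mid-ranks."""
        df = pd.DataFrame(
            [[1.0, 2.0, 2.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 1.0, 3.0, 3.0]],
            index=["a", "b", "c"],
        )
        d = spearman_distance_matrix(df)
        for i, j in itertools.combinations(range(3), 2):
            rho = ss.spearmanr(df.iloc[i], df.iloc[j]).statistic
            assert d.iloc[i, j] == pytest.approx(1 - rho)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)

    def test_constant_row_rejected(self):
        df = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            spearman_distance_matrix(df)

    @given(st.permutations(range(5)))
    def test_invariant_under_monotone_transform(self, perm):
        base = np.array([[0.1, 0.4, 0.2, 0.9, 0.6], list(perm)], dtype=float)
        df1 = pd.DataFrame(base)
        df2 = pd.DataFrame(np.exp(3 * base))  # strictly increasing transform
        d1 = spearman_distance_matrix(df1).to_numpy()
        d2 = spearman_distance_matrix(df2).to_numpy()
        assert np.allclose(d1, d2)


class TestClassicalMDS:
    def test_two_points(self):
        coords = classical_mds(np.array([[0.0, 2.0], [2.0, 0.0]]), dims=1)
        assert sorted(coords[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_round_trip_of_planted_configuration(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(D, dims=2)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_zero_distances_give_zero_coordinates(self):
        coords = classical_mds(np.zeros((4, 4)), dims=2)
        assert np.allclose(coords, 0.0)

    def test_sign_convention_is_deterministic(self, rng):
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c1 = classical_mds(D)
        c2 = classical_mds(D.copy())
        assert np.array_equal(c1, c2)
        for j in range(c1.shape[1]):
            assert c1[np.argmax(np.abs(c1[:, j])), j] >= 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_agrees_with_skbio_pcoa(self, rng):
        """Independent cross-check: principal-coordinates analysis from
        scikit-bio recovers the same configuration up to sign."""
        skbio = pytest.importorskip("skbio")

        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = classical_mds(D, dims=2)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), number_of_dimensions=2
        ).samples.to_numpy()
        for j in range(2):
            assert np.allclose(np.abs(ours[:, j]), np.abs(theirs[:, j]),
                               atol=1e-8)


def exact_signed_rank_p(diffs):
    """2^n sign-enumeration oracle for the two-sided signed-rank test."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = ss.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = d.size
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    p_le = np.mean(stats <= t_obs)
    p_ge = np.mean(stats >= t_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedWilcoxonBH:
    def test_identical_pairs_give_p_one(self):
        x = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        res = paired_wilcoxon_bh(x, x.copy())
        assert res.loc["f", "p"] == 1.0

    def test_bh_hand_example(self):
        x = pd.DataFrame(
            {"a": [1, 2, 3, 4, 5, 6], "b": [1, 2, 3, 4, 5, 6],
             "c": [1, 2, 3, 4, 5, 6]},
            dtype=float,
        )
        # engineer distinct p-values then check the BH step-up directly
        from statsmodels.stats.multitest import multipletests

        ps = np.array([0.01, 0.02, 0.03])
        q = multipletests(ps, method="fdr_bh")[1]
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_exact_p_matches_sign_enumeration(self, rng):
        diffs = np.array([1.5, -0.5, 2.5, 3.5, -1.0, 2.0])
        x = pd.DataFrame({"f": diffs}, index=range(6))
        y = pd.DataFrame({"f": np.zeros(6)}, index=range(6))
        res = paired_wilcoxon_bh(x, y)
        assert res.loc["f", "p"] == pytest.approx(exact_signed_rank_p(diffs))

    def test_unmatched_subjects_rejected(self):
        x = pd.DataFrame({"f": [1.0]}, index=["a"])
        y = pd.DataFrame({"f": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            paired_wilcoxon_bh(x, y)

    def test_bh_monotone_in_sorted_order(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 6)) + 0.5)
        y = pd.DataFrame(rng.normal(size=(8, 6)))
        res = paired_wilcoxon_bh(x, y)
        order = res["p"].sort_values().index
        q_sorted = res.loc[order, "q"].to_numpy()
        assert np.all(np.diff(q_sorted) >= -1e-12)


class TestCarryover:
    def test_identical_arms_give_p_one(self):
        d = {"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0}
        arm = {"a": "A", "b": "A", "c": "B", "d": "B"}
        _, p = carryover_check(d, arm)
        assert p == pytest.approx(1.0)

    def test_fully_separated_arms_exact_p(self):
        d = {f"a{i}": v for i, v in enumerate([1, 2, 3, 4])}
        d |= {f"b{i}": v for i, v in enumerate([5, 6, 7, 8])}
        arm = {k: ("A" if k.startswith("a") else "B") for k in d}
        _, p = carryover_check(d, arm)
        assert p == pytest.approx(2 / 70)

    def test_symmetric_under_arm_swap(self):
        d = {"a": 0.3, "b": 0.9, "c": 0.5, "d": 0.1, "e": 0.7}
        arm = {"a": "A", "b": "A", "c": "B", "d": "B", "e": "B"}
        swapped = {k: ("B" if v == "A" else "A") for k, v in arm.items()}
        assert carryover_check(d, arm)[1] == pytest.approx(
            carryover_check(d, swapped)[1]
        )

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            carryover_check({"a": 1.0, "b": 2.0, "c": 3.0},
                            {"a": "A", "b": "B", "c": "B"})


class TestResponderScore:
    def test_one_week_hand_example(self):
        assert responder_score(c1=10, c2=10, c3=0, t1=10, t2=14, t3=0,
                               horizon="1wk") == pytest.approx(0.4)

    def test_two_week_hand_example(self):
        assert responder_score(c1=12, c2=0, c3=14, t1=8, t2=0, t3=6,
                               horizon="2wk") == pytest.approx(-0.4)

    def test_flat_profile_scores_zero(self):
        assert responder_score(5, 5, 5, 5, 5, 5, "1wk") == 0.0
        assert responder_score(5, 5, 5, 5, 5, 5, "2wk") == 0.0

    def test_zero_baseline_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = responder_score(0, 1, 1, 0, 1, 1, "1wk")
        assert math.isnan(out)


class TestFoldChanges:
    def _t1(self, rows):
        return pd.DataFrame(rows).T.rename(columns=lambda i: f"f{i}")

    def test_ratio_of_group_means(self):
        t1 = pd.DataFrame({"f0": [2.0, 4.0, 1.0, 3.0, 2.0]},
                          index=["s1", "s2", "n1", "n2", "w1"])
        labels = {"s1": "SR", "s2": "SR", "n1": "NR", "n2": "NR", "w1": "WR"}
        fc = fold_changes(t1, labels)
        assert fc.loc["f0", "FCs"] == pytest.approx(1.5)
        assert fc.loc["f0", "FCw"] == pytest.approx(1.0)

    def test_zero_group_mean_uses_pseudocount(self):
        t1 = pd.DataFrame({"f0": [0.0, 0.0, 2.0, 2.0, 1.0],
                           "f1": [4.0, 2.0, 1.0, 1.0, 1.0]},
                          index=["s1", "s2", "n1", "n2", "w1"])
        labels = {"s1": "SR", "s2": "SR", "n1": "NR", "n2": "NR", "w1": "WR"}
        fc = fold_changes(t1, labels)
        eps = 0.5 * 1.0  # half the smallest positive value in the table
        assert fc.loc["f0", "FCs"] == pytest.approx((0 + eps) / (2 + eps))

    def test_missing_sr_group_gives_nan_fcs(self):
        t1 = pd.DataFrame({"f0": [1.0, 2.0, 3.0]}, index=["n1", "n2", "w1"])
        labels = {"n1": "NR", "n2": "NR", "w1": "WR"}
        fc = fold_changes(t1, labels)
        assert math.isnan(fc.loc["f0", "FCs"])
        assert fc.loc["f0", "FCw"] == pytest.approx(2.0)

    def test_empty_nr_rejected(self):
        t1 = pd.DataFrame({"f0": [1.0, 2.0]}, index=["s1", "w1"])
        with pytest.raises(ValueError):
            fold_changes(t1, {"s1": "SR", "w1": "WR"})


def jt_enumeration_oracle(groups):
    """Enumerate all distinct assignments of the pooled values to the group
    sizes via permutations (deduplicated)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    seen = {}
    for perm in itertools.permutations(range(pooled.size)):
        parts = []
        start = 0
        for sz in sizes:
            parts.append(tuple(sorted(perm[start:start + sz])))
            start += sz
        key = tuple(parts)
        if key in seen:
            continue
        vals = [pooled[list(p)] for p in parts]
        j = 0.0
        for a, b in itertools.combinations(range(len(vals)), 2):
            x, y = vals[a], vals[b]
            j += (x[:, None] < y[None, :]).sum()
            j += 0.5 * (x[:, None] == y[None, :]).sum()
        seen[key] = j
    return np.array(list(seen.values()))


class TestJonckheereTerpstra:
    def test_maximal_separation(self):
        j, p = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], method="exact")
        assert j == 12.0
        null = jt_enumeration_oracle([[1, 2], [3, 4], [5, 6]])
        expected = min(1.0, 2 * min((null >= 12).mean(), (null <= 12).mean()))
        assert p == pytest.approx(expected)
        assert p == pytest.approx(2 / 90)

    def test_all_equal_observations(self):
        j, p = jonckheere_terpstra([[1, 1], [1, 1], [1, 1]], method="exact")
        assert j == 6.0  # half of the 12 cross-group pairs
        assert p == 1.0

    def test_reversed_groups_symmetric_p(self):
        asc = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], method="exact")
        desc = jonckheere_terpstra([[5, 6], [3, 4], [1, 2]], method="exact")
        assert desc[0] == 0.0
        assert desc[1] == pytest.approx(asc[1])

    @pytest.mark.parametrize("groups", [
        ([1.0, 3.0, 2.5], [2.0, 4.0], [5.0, 3.5, 6.0]),
        ([1, 1, 2], [2, 3], [3, 3, 4]),
        ([0.1, 0.2], [0.15, 0.3], [0.05]),
    ])
    def test_exact_p_matches_enumeration_oracle(self, groups):
        j, p = jonckheere_terpstra(groups, method="exact")
        null = jt_enumeration_oracle(groups)
        tol = 1e-9
        expected = min(1.0, 2 * min((null >= j - tol).mean(),
                                    (null <= j + tol).mean()))
        assert p == pytest.approx(expected)

    def test_permutation_close_to_exact(self):
        groups = ([1.0, 3.0, 2.5], [2.0, 4.0], [5.0, 3.5, 6.0])
        _, p_exact = jonckheere_terpstra(groups, method="exact")
        _, p_perm = jonckheere_terpstra(groups, method="permutation",
                                        n_permutations=20_000, seed=1)
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_perm - p_exact) < 3 * se + 1e-4

    def test_asymptotic_reasonable_on_larger_groups(self, rng):
        g1 = rng.normal(0, 1, 15)
        g2 = rng.normal(0.8, 1, 15)
        g3 = rng.normal(1.6, 1, 15)
        _, p = jonckheere_terpstra([g1, g2, g3], method="asymptotic")
        assert p < 0.01

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=4),
           st.lists(st.floats(-5, 5), min_size=2, max_size=4))
    def test_j_plus_j_reversed_is_pair_count(self, a, b):
        j_f, _ = jonckheere_terpstra([a, b], method="asymptotic")
        j_r, _ = jonckheere_terpstra([b[::-1], a[::-1]], method="asymptotic")
        assert j_f + j_r == pytest.approx(len(a) * len(b))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2, 3]])


class TestSelectTrendFeatures:
    def _fc(self, rows):
        return pd.DataFrame(rows, columns=["FCs", "FCw"])

    def test_increasing_rule(self):
        fc = pd.DataFrame({"FCs": [2.0], "FCw": [1.5]}, index=["g1"])
        out = select_trend_features(fc, {"g1": (10.0, 0.01)})
        assert len(out) == 1 and out[0].direction == "increasing"

    def test_ordering_violation_excluded(self):
        fc = pd.DataFrame({"FCs": [2.0], "FCw": [0.9]}, index=["g1"])
        assert select_trend_features(fc, {"g1": (10.0, 0.001)}) == []

    def test_decreasing_rule_and_alpha(self):
        fc = pd.DataFrame({"FCs": [0.4, 0.5], "FCw": [0.7, 0.8]},
                          index=["g1", "g2"])
        out = select_trend_features(
            fc, {"g1": (1.0, 0.01), "g2": (1.0, 0.2)}, alpha=0.05
        )
        assert [t.feature for t in out] == ["g1"]
        assert out[0].direction == "decreasing"


class TestFeatureTable:
    def test_genus_rows_renormalised_with_warning(self):
        idx = pd.MultiIndex.from_tuples([("s1", "T1")],
                                        names=["subject_id", "timepoint"])
        df = pd.DataFrame([[0.5, 0.4]], index=idx, columns=["a", "b"])
        with pytest.warns(UserWarning, match="renormalising"):
            t = FeatureTable(df, kind="genus_relab")
        assert t.values.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_negative_values_rejected(self):
        idx = pd.MultiIndex.from_tuples([("s1", "T1")],
                                        names=["subject_id", "timepoint"])
        df = pd.DataFrame([[-0.1, 1.1]], index=idx, columns=["a", "b"])
        with pytest.raises(ValueError):
            FeatureTable(df, kind="metabolite_content")

    def test_tsv_round_trip(self, tmp_path):
        idx = pd.MultiIndex.from_tuples(
            [("s1", "T1"), ("s1", "C1")], names=["subject_id", "timepoint"]
        )
        df = pd.DataFrame([[0.6, 0.4], [0.3, 0.7]], index=idx,
                          columns=["a", "b"])
        t = FeatureTable(df, kind="genus_relab")
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        back = FeatureTable.from_tsv(path, kind="genus_relab")
        assert np.allclose(back.values.to_numpy(), t.values.to_numpy())
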