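"""Stability, consensus, permutation machinery and group statistics
against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from nirsgraph.explain import EdgeImportanceMap
from nirsgraph.stats import (
    FoldEdgeSets,
    ancova_age_adjusted,
    bh_fdr,
    channelwise_ancova,
    consensus_network,
    edge_group_tests,
    edge_support,
    fold_top_edges,
    jaccard_stability,
    label_permutation_test,
)


def _maps(sets_by_fold):
    return {
        k: EdgeImportanceMap(phi={e: 1.0 - i * 0.01 for i, e in enumerate(edges)})
        for k, edges in sets_by_fold.items()
    }


class TestFoldTopEdges:
    def test_top_n_selection(self):
        imp = {0: EdgeImportanceMap(phi={("a", "b"): 0.9, ("a", "c"): 0.5, ("b", "c"): 0.1}),
               1: EdgeImportanceMap(phi={("a", "b"): 0.2, ("a", "c"): 0.8, ("b", "c"): 0.5})}
        sets = fold_top_edges(imp, top_n=2, top_fraction=None)
        assert sets.sets[0] == frozenset({("a", "b"), ("a", "c")})
        assert sets.sets[1] == frozenset({("a", "c"), ("b", "c")})

    def test_tie_broken_lexicographically(self):
        imp = {0: EdgeImportanceMap(phi={("b", "c"): 0.5, ("a", "b"): 0.5, ("a", "c"): 0.9}),
               1: EdgeImportanceMap(phi={("a", "b"): 1.0})}
        sets = fold_top_edges(imp, top_n=2, top_fraction=None)
        assert sets.sets[0] == frozenset({("a", "c"), ("a", "b")})

    def test_top_fraction_floor_arithmetic(self):
        # 1128 possible 48-node edges at 10% -> floor(112.8) = 112
        phi = {(f"c{i}", f"d{i}"): float(i) for i in range(1128)}
        imp = {0: EdgeImportanceMap(phi=phi), 1: EdgeImportanceMap(phi=phi)}
        sets = fold_top_edges(imp, top_fraction=0.10)
        assert len(sets.sets[0]) == 112

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            fold_top_edges({0: EdgeImportanceMap(phi={})})


class TestJaccardStability:
    def test_identical_disjoint_and_worked_example(self):
        sets = FoldEdgeSets(sets={0: frozenset({"x"}), 1: frozenset({"x"})})
        assert jaccard_stability(sets)["mean"] == 1.0
        sets = FoldEdgeSets(sets={0: frozenset({"x"}), 1: frozenset({"y"})})
        assert jaccard_stability(sets)["mean"] == 0.0
        sets = FoldEdgeSets(sets={0: frozenset({"ab", "bc"}), 1: frozenset({"ab", "cd"})})
        assert jaccard_stability(sets)["mean"] == pytest.approx(1 / 3)

    def test_empty_union_convention(self):
        sets = FoldEdgeSets(sets={0: frozenset(), 1: frozenset()})
        assert jaccard_stability(sets)["mean"] == 1.0


class TestConsensus:
    def test_support_ratio_and_retention(self):
        sets = FoldEdgeSets(sets={
            k: frozenset({"e1"} | ({"e2"} if k < 2 else set())) for k in range(5)
        })
        # e1 in 5/5, e2 in 2/5
        net = consensus_network(sets, rho=0.6)
        assert net.edges["e1"] == 1.0
        assert "e2" not in net.edges
        assert net.support["e2"] == pytest.approx(0.4)

    def test_four_of_five_folds_is_retained_at_point_six(self):
        sets = FoldEdgeSets(sets={k: frozenset({"e"} if k < 4 else set()) for k in range(5)})
        net = consensus_network(sets, rho=0.6)
        assert net.edges["e"] == pytest.approx(0.80)

    def test_rho_one_is_fold_intersection_and_monotone(self):
        rng = np.random.default_rng(0)
        universe = [f"e{i}" for i in range(30)]
        sets = FoldEdgeSets(sets={
            k: frozenset(e for e in universe if rng.random() < 0.5) for k in range(5)
        })
        inter = frozenset.intersection(*sets.sets.values())
        assert set(consensus_network(sets, rho=1.0).edges) == set(inter)
        prev = None
        for rho in (0.2, 0.4, 0.6, 0.8, 1.0):
            edges = set(consensus_network(sets, rho).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestLabelPermutation:
    def test_p_values_count_exceedances(self):
        """Pipeline stub whose permuted supports are deterministic: p equals
        a hand recount of permutations meeting the observed support."""
        edges = ["e1", "e2"]

        def pipeline(graphs, labels, seed):
            # "e1" is selected by every fold iff labels are in original order;
            # "e2" is always selected by exactly 3 folds
            original = np.array_equal(labels, np.arange(len(labels)))
            sets = {}
            for k in range(5):
                s = {"e2"} if k < 3 else set()
                if original or (labels[0] % 3 == 0):
                    s.add("e1")
                sets[k] = frozenset(s)
            return FoldEdgeSets(sets=sets)

        labels = np.arange(9)
        df = label_permutation_test(pipeline, None, labels, n_perm=60, seed=4)
        row1 = df.set_index("edge").loc["e1"]
        row2 = df.set_index("edge").loc["e2"]
        assert row2["p_perm"] == 1.0  # e2 support identical under every permutation
        # recount e1 exceedances with the same RNG stream
        from nirsgraph.config import substream
        rng = substream(4, "label_permutations")
        count = 0
        for _ in range(60):
            perm = rng.permutation(labels)
            rng.integers(0, 2**31 - 1)
            if perm[0] % 3 == 0:
                count += 1
        assert row1["p_perm"] == pytest.approx(count / 60)

    def test_low_n_perm_warns(self):
        def pipeline(graphs, labels, seed):
            return FoldEdgeSets(sets={0: frozenset({"e"}), 1: frozenset()})

        with pytest.warns(UserWarning, match="n_perm"):
            label_permutation_test(pipeline, None, np.arange(6), n_perm=5, seed=0)


class TestBHFDR:
    def test_worked_step_up(self):
        out = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        np.testing.assert_allclose(out["p_adjusted"], 0.04)
        assert out["significant"].all()

    def test_single_p_identity_and_all_ones(self):
        assert bh_fdr(np.array([0.04]))["p_adjusted"][0] == pytest.approx(0.04)
        assert not bh_fdr(np.ones(5))["significant"].any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_brute_force_step_up(self, ps):
        p = np.array(ps)
        got = bh_fdr(p, q=0.05)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            adj[i] = running
        np.testing.assert_allclose(got["p_adjusted"], adj, atol=1e-12)
        np.testing.assert_array_equal(got["significant"], adj <= 0.05)


def brute_force_kruskal(groups):
    """Eq.-style H with tie correction, computed from scratch."""
    all_vals = np.concatenate(groups)
    N = len(all_vals)
    ranks = sstats.rankdata(all_vals)
    rbar = (N + 1) / 2
    idx = 0
    H = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        H += len(g) * (r.mean() - rbar) ** 2
    H *= 12 / (N * (N + 1))
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return H / tie


class TestGroupTests:
    def test_kruskal_worked_example(self):
        # {1,2},{3,4},{5,6}: H = (12/42) * (2*4 + 0 + 2*4) = 4.571
        vals = {("a", "b"): {"HC": np.array([1, 2.0]), "MCI": np.array([3, 4.0]),
                             "AD": np.array([5, 6.0])}}
        df = edge_group_tests(vals)
        assert df.iloc[0]["statistic"] == pytest.approx(4.571, abs=0.001)

    def test_kruskal_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            groups = [np.round(rng.normal(size=rng.integers(3, 8)), 1) for _ in range(3)]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue
            try:
                H, _ = sstats.kruskal(*groups)
            except ValueError:
                continue
            assert H == pytest.approx(brute_force_kruskal(groups), abs=1e-9)

    def test_identical_groups_are_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = edge_group_tests({("a", "b"): {"HC": x, "MCI": x.copy()}}, pair=("HC", "MCI"))
        assert df.iloc[0]["p"] > 0.9

    def test_direction_sign_reported(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(0, 1, 20)
        hi = rng.normal(3, 1, 20)
        df = edge_group_tests({("a", "b"): {"MCI": lo, "HC": hi}}, pair=("MCI", "HC"))
        assert df.iloc[0]["direction"] == -1  # MCI - HC < 0

    def test_constant_group_uses_nonparametric_branch(self):
        with pytest.warns(UserWarning, match="nonparametric"):
            df = edge_group_tests(
                {("a", "b"): {"HC": np.ones(5), "MCI": np.arange(5.0)}}, pair=("HC", "MCI")
            )
        assert df.iloc[0]["test"] == "mannwhitney"

    def test_false_positive_rate_calibrated_under_null(self):
        rng = np.random.default_rng(2)
        vals = {
            (f"c{i}", f"d{i}"): {"HC": rng.normal(size=15), "MCI": rng.normal(size=15)}
            for i in range(500)
        }
        df = edge_group_tests(vals, pair=("HC", "MCI"))
        fpr = (df["p"] < 0.05).mean()
        assert fpr == pytest.approx(0.05, abs=0.02)


class TestANCOVA:
    def test_null_group_effect_with_age_trend(self):
        rng = np.random.default_rng(0)
        n = 60
        age = rng.uniform(60, 85, n)
        groups = ["HC", "MCI", "AD"] * (n // 3)
        y = 0.05 * age + rng.normal(0, 0.01, n)
        # construct exact group-mean equality of the age-adjusted feature
        X = np.stack([np.ones(n), age], axis=1)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        for g in ("HC", "MCI", "AD"):
            sel = np.array(groups) == g
            y[sel] -= resid[sel].mean()
        out = ancova_age_adjusted(y, groups, age)
        assert out["p"] > 0.5
        assert out["F_group"] < 1.0
        assert out["F_age"] > 10

    def test_group_shift_power(self):
        # 2 SD planted shift at n = 20 per group: detected in >= 95% of runs
        rng = np.random.default_rng(1)
        hits = 0
        runs = 200
        for _ in range(runs):
            age = rng.uniform(60, 85, 60)
            groups = ["HC"] * 20 + ["MCI"] * 20 + ["AD"] * 20
            y = rng.normal(0, 1, 60)
            y[20:40] += 2.0
            if ancova_age_adjusted(y, groups, age)["p"] < 0.01:
                hits += 1
        assert hits / runs >= 0.95

    def test_age_confound_attenuates_group_effect(self):
        rng = np.random.default_rng(2)
        # ages differ by group; feature is purely age-driven
        age = np.concatenate([rng.normal(65, 2, 20), rng.normal(72, 2, 20),
                              rng.normal(78, 2, 20)])
        groups = ["HC"] * 20 + ["MCI"] * 20 + ["AD"] * 20
        y = 0.1 * age + rng.normal(0, 0.05, 60)
        adjusted = ancova_age_adjusted(y, groups, age)["F_group"]
        f_unadjusted = sstats.f_oneway(y[:20], y[20:40], y[40:])[0]
        assert adjusted < f_unadjusted

    def test_channelwise_wrapper_applies_fdr(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(30, 4))
        groups = ["HC", "MCI", "AD"] * 10
        age = rng.uniform(60, 85, 30)
        df = channelwise_ancova(feats, groups, age)
        assert list(df["channel"]) == [0, 1, 2, 3]
        assert (df["p_adj"] >= df["p"] - 1e-12).all()
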