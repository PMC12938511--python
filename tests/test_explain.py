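"""Edge-importance extraction and the perturbation-based validity test."""

import numpy as np
import pytest

from nirsgraph.config import ChromophoreMode, EdgeType, Group, ModelArch
from nirsgraph.explain import (
    EdgeImportanceMap,
    aggregate_importance,
    head_mean_importance,
    mask_explainer,
    perturbation_test,
)
from nirsgraph.graphs import SubjectGraph
from nirsgraph.nn import autodiff as ad
from nirsgraph.nn.models import ModelSpec
from nirsgraph.nn.training import FoldResult, batch_graphs, evaluate_metrics


def _graph(A, sid="s", group=Group.HC, d=4, rng=None):
    n = A.shape[0]
    X = (rng or np.random.default_rng(0)).standard_normal((n, d))
    return SubjectGraph(sid, group, [f"Ch{i+1}" for i in range(n)], A, X,
                        EdgeType.COMPLEXITY_FC, "FS4", ChromophoreMode.HBO, 0.3)


class TestHeadMean:
    def test_worked_head_average(self):
        # head coefficients {0.1, 0.2, 0.3, 0.4} on one edge -> 0.25
        att = np.zeros((4, 3, 3))
        att[:, 0, 1] = [0.1, 0.2, 0.3, 0.4]
        assert head_mean_importance(att)[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force_on_random_tensors(self):
        rng = np.random.default_rng(1)
        att = rng.random((5, 4, 6, 6))
        got = head_mean_importance(att)
        want = np.stack([att[b].mean(axis=0) for b in range(5)])
        np.testing.assert_allclose(got, want)


class TestImportanceMap:
    def test_ranking_and_ties(self):
        m = EdgeImportanceMap(phi={("a", "b"): 0.9, ("a", "c"): 0.5, ("b", "c"): 0.5})
        assert m.top_edges(n=2) == [("a", "b"), ("a", "c")]  # lexicographic tie-break
        assert m.top_edges(fraction=1 / 3) == [("a", "b")]

    def test_aggregation_means_over_maps(self):
        m1 = EdgeImportanceMap(phi={("a", "b"): 0.2})
        m2 = EdgeImportanceMap(phi={("a", "b"): 0.6, ("a", "c"): 1.0})
        agg = aggregate_importance([m1, m2])
        assert agg.phi[("a", "b")] == pytest.approx(0.4)
        assert agg.phi[("a", "c")] == pytest.approx(1.0)


class _EdgeDependentModel:
    """Toy differentiable model whose output depends only on edge (0, 1)."""

    params: list = []

    def forward(self, X, A, node_mask, training=False, rng=None):
        A = ad.ensure(A)
        sel = np.zeros(A.shape[-2:]); sel[0, 1] = sel[1, 0] = 1.0
        strength = ad.tsum(ad.mul(A, sel), axis=(-2, -1))      # [B]
        B = A.shape[0]
        out0 = ad.reshape(ad.mul(strength, 10.0), (B, 1))
        zeros = ad.Tensor(np.zeros((B, 2)))
        return ad.concat([out0, zeros], axis=1)


class _ConstantModel:
    params: list = []

    def forward(self, X, A, node_mask, training=False, rng=None):
        B = np.asarray(A.data if isinstance(A, ad.Tensor) else A).shape[0]
        return ad.Tensor(np.tile([5.0, 0.0, 0.0], (B, 1)))


def _dense_graph(n=6, rng=None):
    rng = rng or np.random.default_rng(0)
    A = np.triu(rng.uniform(0.3, 0.9, (n, n)), 1)
    A = A + A.T
    np.fill_diagonal(A, 0)
    return A


class TestMaskExplainer:
    def test_edge_dependent_model_ranks_that_edge_first(self):
        A = _dense_graph()
        batch = batch_graphs([_graph(A)])
        spec = ModelSpec(arch=ModelArch.GCN)
        imp = mask_explainer(_EdgeDependentModel(), batch, spec, steps=150, seed=0)
        assert imp.top_edges(n=1) == [("Ch1", "Ch2")]
        # cross-check by exhaustive single-edge deletion: only (0,1) changes logits
        m = _EdgeDependentModel()
        base = m.forward(None, batch.A[0], batch.node_mask).data
        for i, j in zip(*np.triu_indices(6, 1)):
            Am = batch.A[0].copy()
            Am[0, i, j] = Am[0, j, i] = 0.0
            changed = not np.allclose(m.forward(None, Am, batch.node_mask).data, base)
            assert changed == ((i, j) == (0, 1))

    def test_constant_model_leaves_mask_near_uniform(self):
        A = _dense_graph()
        batch = batch_graphs([_graph(A)])
        spec = ModelSpec(arch=ModelArch.GCN)
        imp = mask_explainer(_ConstantModel(), batch, spec, steps=50,
                             sparsity=0.0, entropy_weight=0.0, seed=0)
        vals = np.array(list(imp.phi.values()))
        assert np.abs(vals - 0.5).max() < 0.02  # stays at sigmoid(~0)

    def test_extreme_sparsity_drives_mask_to_zero(self):
        A = _dense_graph()
        batch = batch_graphs([_graph(A)])
        spec = ModelSpec(arch=ModelArch.GCN)
        imp = mask_explainer(_ConstantModel(), batch, spec, steps=300, lr=0.1,
                             sparsity=1e3, entropy_weight=0.0, seed=0)
        assert max(imp.phi.values()) < 0.05


def _fold_results(graphs, model, spec):
    batch = batch_graphs(graphs)
    m = evaluate_metrics(batch.labels, np.argmax(
        model.forward(batch.X[0], batch.A[0], batch.node_mask).data, axis=1))
    return [FoldResult(
        fold_id=0, train_ids=[], test_ids=batch.subject_ids,
        y_true=batch.labels, y_pred=batch.labels, macro_f1=m["macro_f1"],
        per_class_recall=m["per_class_recall"], confusion=m["confusion"],
        model=model, feature_stats=(0, 1), test_batch=batch,
    )]


class TestPerturbation:
    def _graphs(self):
        rng = np.random.default_rng(2)
        gs = []
        for i, grp in enumerate([Group.HC, Group.MCI, Group.AD] * 4):
            gs.append(_graph(_dense_graph(rng=rng), sid=f"s{i}", group=grp, rng=rng))
        return gs

    def test_probability_bounds_and_null_behaviour(self):
        gs = self._graphs()
        spec = ModelSpec(arch=ModelArch.GCN)
        fr = _fold_results(gs, _ConstantModel(), spec)
        imp = EdgeImportanceMap(phi={(f"Ch{i+1}", f"Ch{j+1}"): float(10 - i - j)
                                     for i, j in zip(*np.triu_indices(6, 1))})
        out = perturbation_test(fr, imp, spec, top_frac=0.10, n_random=50, seed=0)
        # a constant model is unaffected by any deletion
        assert out["delta_topk"] == 0.0
        assert np.all(np.asarray(out["delta_random"]) == 0.0)
        assert out["p_empirical"] == 1.0  # all null draws tie the observed delta

    def test_random_importance_is_calibrated(self):
        """Importance unrelated to the model: p should rarely be small."""
        gs = self._graphs()
        spec = ModelSpec(arch=ModelArch.GCN)
        rng = np.random.default_rng(5)

        class _NoisyModel:
            params: list = []

            def forward(self, X, A, node_mask, training=False, rng_=None):
                a = A.data if isinstance(A, ad.Tensor) else np.asarray(A)
                s = a.sum(axis=(1, 2))
                logits = np.stack([np.sin(7 * s), np.cos(5 * s), np.sin(3 * s + 1)], 1)
                return ad.Tensor(logits)

        fr = _fold_results(gs, _NoisyModel(), spec)
        small = 0
        reps = 20
        for rep in range(reps):
            phi = {(f"Ch{i+1}", f"Ch{j+1}"): float(rng.random())
                   for i, j in zip(*np.triu_indices(6, 1))}
            out = perturbation_test(fr, EdgeImportanceMap(phi=phi), spec,
                                    top_frac=0.10, n_random=60, seed=rep)
            assert 0.0 <= out["p_empirical"] <= 1.0
            small += out["p_empirical"] < 0.05
        assert small / reps <= 0.15

    def test_zero_deletion_fraction_rejected(self):
        gs = self._graphs()
        spec = ModelSpec(arch=ModelArch.GCN)
        fr = _fold_results(gs, _ConstantModel(), spec)
        imp = EdgeImportanceMap(phi={})
        with pytest.raises(ValueError, match="zero edges"):
            perturbation_test(fr, imp, spec, top_frac=0.001, n_random=5, seed=0)
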