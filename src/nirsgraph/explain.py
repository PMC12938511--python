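"""Edge-level explainability and perturbation validation.

For attention models, per-edge importance is the attention coefficient
averaged over heads (then over layers and, for group maps, subjects).
For non-attention models a soft edge mask is optimized to preserve the
model's own prediction while shrinking the mask (sparsity + entropy
regularization). Either importance ranking is then validated by a
perturbation test: delete the top-K (10%) edges by importance and compare
the performance drop against equal-count random deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Group, ModelArch, substream
from .nn import autodiff as ad
from .nn.models import GAT, ModelSpec, weighted_cross_entropy
from .nn.training import Ensemble, FoldResult, GraphBatch, _forward, evaluate_metrics, predict

EdgeKey = tuple[str, str]


@dataclass
class EdgeImportanceMap:
    """phi importance per edge, keyed by unordered channel-label pair."""

    phi: dict[EdgeKey, float]
    provenance: dict = field(default_factory=dict)

    def top_edges(self, n: int | None = None, fraction: float | None = None) -> list[EdgeKey]:
        """Edges ranked by phi descending; ties broken lexicographically."""
        ranked = sorted(self.phi.items(), key=lambda kv: (-kv[1], kv[0]))
        if fraction is not None:
            n = int(len(ranked) * fraction)
        if n is None:
            n = len(ranked)
        return [k for k, _ in ranked[:n]]


def _edge_key(a: str, b: str) -> EdgeKey:
    return (a, b) if a <= b else (b, a)


def head_mean_importance(attention: np.ndarray) -> np.ndarray:
    """Mean over attention heads: [heads, N, N] (or [B, heads, N, N]) -> [.., N, N]."""
    return np.asarray(attention).mean(axis=-3)


def attention_importance(
    model: GAT,
    batch: GraphBatch,
    spec: ModelSpec,
    layer_aggregate: str = "mean",
) -> tuple[list[EdgeImportanceMap], dict[str, EdgeImportanceMap]]:
    """Per-subject and per-group edge-importance maps from GAT attention.

    Per edge: mean of the attention coefficients over heads, then over
    layers ("mean") or the last layer only ("last"). Before aggregation,
    each destination row is renormalized over actual (non-self) edges so
    self-loop mass does not dilute edge scores; the directed matrix is
    symmetrized by averaging the two directions.
    """
    members = model.members if isinstance(model, Ensemble) else [model]
    if not all(isinstance(m, GAT) for m in members):
        raise TypeError("model has no attention; use mask_explainer instead")
    layer_stacks = []
    for m in members:
        _forward(m, batch, spec, training=False)
        layer_stacks.append([a.copy() for a in m.last_attention])
    # mean over ensemble members per layer: list of [B, heads, N, N]
    layers = [np.mean([st[i] for st in layer_stacks], axis=0)
              for i in range(len(layer_stacks[0]))]
    per_layer = [head_mean_importance(a) for a in layers]   # [B, N, N]
    stack = np.stack(per_layer)
    phi_bnn = stack[-1] if layer_aggregate == "last" else stack.mean(axis=0)

    subject_maps: list[EdgeImportanceMap] = []
    group_acc: dict[str, dict[EdgeKey, list[float]]] = {}
    for i in range(batch.n_graphs):
        n = int(batch.node_mask[i].sum())
        A = batch.A[0][i, :n, :n]
        P = phi_bnn[i, :n, :n].copy()
        np.fill_diagonal(P, 0.0)
        rowsum = P.sum(axis=1, keepdims=True)
        P = np.divide(P, rowsum, out=np.zeros_like(P), where=rowsum > 0)
        sym = 0.5 * (P + P.T)
        labels = batch.node_labels[i]
        phi = {}
        for a, b in zip(*np.nonzero(np.triu(A, 1))):
            key = _edge_key(labels[a], labels[b])
            phi[key] = float(sym[a, b])
        m = EdgeImportanceMap(
            phi=phi,
            provenance={"method": "attention", "subject": batch.subject_ids[i],
                        "label": int(batch.labels[i])},
        )
        subject_maps.append(m)
        gname = list(Group)[batch.labels[i]].value
        acc = group_acc.setdefault(gname, {})
        for k, v in phi.items():
            acc.setdefault(k, []).append(v)
    group_maps = {
        g: EdgeImportanceMap(
            phi={k: float(np.mean(v)) for k, v in acc.items()},
            provenance={"method": "attention", "group": g},
        )
        for g, acc in group_acc.items()
    }
    return subject_maps, group_maps


def aggregate_importance(maps: list[EdgeImportanceMap]) -> EdgeImportanceMap:
    """Mean phi across maps (edges missing from a map contribute nothing)."""
    acc: dict[EdgeKey, list[float]] = {}
    for m in maps:
        for k, v in m.phi.items():
            acc.setdefault(k, []).append(v)
    return EdgeImportanceMap(
        phi={k: float(np.mean(v)) for k, v in acc.items()},
        provenance={"method": "aggregate", "n_maps": len(maps)},
    )


def mask_explainer(
    model,
    batch: GraphBatch,
    spec: ModelSpec,
    graph_index: int = 0,
    steps: int = 200,
    lr: float = 0.01,
    sparsity: float = 0.005,
    entropy_weight: float = 0.001,
    seed: int = 0,
) -> EdgeImportanceMap:
    """Soft-edge-mask explanation for one graph of a batch.

    Learns a per-edge sigmoid mask minimizing the cross-entropy of the
    model's *own original prediction* on the masked graph, plus an L1
    sparsity term and an element-wise entropy term that pushes the mask
    toward a crisp subgraph. phi = final mask values. Deterministic under
    ``seed``.
    """
    one = batch.subset(np.array([graph_index]))
    orig_pred = predict(model, one, spec)
    if isinstance(model, Ensemble):
        model = model.members[0]  # optimize the mask through one member
    n = int(one.node_mask[0].sum())
    A0 = [a.copy() for a in one.A]
    edge_mask_np = (A0[0][0] > 0)

    rng = substream(seed, "mask_explainer")
    logits_init = 0.01 * rng.standard_normal(A0[0][0].shape)
    logits_init = 0.5 * (logits_init + logits_init.T)
    mask_logits = ad.Tensor(logits_init, requires_grad=True)
    opt = ad.Adam([mask_logits], lr=lr)
    weights = np.ones(3)

    n_edges = max(edge_mask_np.sum(), 1)
    for _ in range(steps):
        opt.zero_grad()
        m = ad.sigmoid(mask_logits)
        m_sym = ad.mul(ad.add(m, ad.transpose(m, (1, 0))), 0.5)
        masked_A = [
            ad.reshape(ad.mul(ad.ensure(a[0]), m_sym), (1,) + a[0].shape) for a in A0
        ]
        masked = GraphBatch(
            X=one.X, A=masked_A,  # type: ignore[arg-type]  # models accept Tensors
            node_mask=one.node_mask, labels=one.labels,
            subject_ids=one.subject_ids, node_labels=one.node_labels,
        )
        out = _forward(model, masked, spec, training=False)
        ce = weighted_cross_entropy(out, orig_pred, weights)
        mvals = ad.mul(m, edge_mask_np)
        l1 = ad.mul(ad.tsum(mvals), sparsity / n_edges)
        ent = ad.mul(
            ad.tsum(ad.mul(ad.mul(mvals, -1.0), log_clip(mvals))),
            entropy_weight / n_edges,
        )
        loss = ad.add(ad.add(ce, l1), ent)
        loss.backward()
        opt.step()
    s = 1.0 / (1.0 + np.exp(-mask_logits.data))
    m_final = 0.5 * (s + s.T)

    labels = one.node_labels[0]
    phi = {}
    for a, b in zip(*np.nonzero(np.triu(A0[0][0, :n, :n], 1))):
        phi[_edge_key(labels[a], labels[b])] = float(m_final[a, b])
    return EdgeImportanceMap(
        phi=phi,
        provenance={"method": "mask", "subject": one.subject_ids[0]},
    )


def log_clip(t: ad.Tensor, eps: float = 1e-9) -> ad.Tensor:
    return ad.log(ad.add(t, eps))


def _delete_edges(A: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    out = A.copy()
    for i, j in pairs:
        out[i, j] = 0.0
        out[j, i] = 0.0
    return out


def _graph_edge_list(A: np.ndarray) -> list[tuple[int, int]]:
    return [tuple(ij) for ij in np.argwhere(np.triu(A, 1) != 0)]


def perturbation_test(
    fold_results: list[FoldResult],
    importance: EdgeImportanceMap,
    spec: ModelSpec,
    top_frac: float = 0.10,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Top-K edge-deletion sensitivity test against a random-deletion null.

    For each cross-validation fold, the fold's model is evaluated on its
    held-out graphs intact, with the top ``top_frac`` of each graph's
    edges (ranked by the supplied importance map) deleted, and with the
    same number of randomly chosen edges deleted (``n_random`` draws).
    Reports Delta_topk = intact - topk macro-F1 (pooled over folds), the
    null Delta distribution and the empirical p = #(Delta_rand >=
    Delta_topk) / n_random.
    """
    rng = substream(seed, "random_deletions")

    def pooled_f1(batches_A) -> float:
        y_true, y_pred = [], []
        for r, A_list in zip(fold_results, batches_A):
            b = r.test_batch
            mod_batch = GraphBatch(X=b.X, A=A_list, node_mask=b.node_mask,
                                   labels=b.labels, subject_ids=b.subject_ids,
                                   node_labels=b.node_labels)
            y_true.append(b.labels)
            y_pred.append(predict(r.model, mod_batch, spec))
        m = evaluate_metrics(np.concatenate(y_true), np.concatenate(y_pred))
        return m["macro_f1"]

    # per fold+graph: edge list, per-edge phi, deletion count
    per_fold_edges = []
    total_deleted = 0
    for r in fold_results:
        b = r.test_batch
        entries = []
        for i in range(b.n_graphs):
            edges = _graph_edge_list(b.A[0][i])
            labels = b.node_labels[i]
            ranked = sorted(
                edges,
                key=lambda e: (-importance.phi.get(_edge_key(labels[e[0]], labels[e[1]]), 0.0),
                               labels[e[0]], labels[e[1]]),
            )
            k = int(len(edges) * top_frac)
            entries.append((edges, ranked[:k]))
            total_deleted += k
        per_fold_edges.append(entries)
    if total_deleted == 0:
        raise ValueError("top_frac deletes zero edges")

    intact = pooled_f1([r.test_batch.A for r in fold_results])

    topk_A = []
    for r, entries in zip(fold_results, per_fold_edges):
        A_list = [a.copy() for a in r.test_batch.A]
        for i, (_, topk) in enumerate(entries):
            for t in range(len(A_list)):
                A_list[t][i] = _delete_edges(A_list[t][i], topk)
        topk_A.append(A_list)
    delta_topk = intact - pooled_f1(topk_A)

    deltas = np.empty(n_random)
    for trial in range(n_random):
        rand_A = []
        for r, entries in zip(fold_results, per_fold_edges):
            A_list = [a.copy() for a in r.test_batch.A]
            for i, (edges, topk) in enumerate(entries):
                sel = rng.choice(len(edges), size=len(topk), replace=False) if edges else []
                pairs = [edges[s] for s in sel]
                for t in range(len(A_list)):
                    A_list[t][i] = _delete_edges(A_list[t][i], pairs)
            rand_A.append(A_list)
        deltas[trial] = intact - pooled_f1(rand_A)

    p = float((deltas >= delta_topk).mean())
    return {
        "intact_macro_f1": intact,
        "delta_topk": float(delta_topk),
        "delta_random": deltas,
        "delta_random_mean": float(deltas.mean()),
        "p_empirical": p,
    }
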