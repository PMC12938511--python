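"""Training and evaluation under stratified subject-independent CV.

Folds are stratified by diagnostic group at the subject level, node
features are z-scored with training-fold statistics only, and the loss is
class-weighted inversely to training-fold class frequencies. Given a
seed, fold assignment, parameter initialization and the entire weight
trajectory are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, recall_score
from sklearn.model_selection import StratifiedKFold

from ..config import GROUPS, ModelArch, substream, substream_seed
from ..graphs import SubjectGraph
from . import autodiff as ad
from .models import ModelSpec, build_model, weighted_cross_entropy

LABEL_OF = {g: i for i, g in enumerate(GROUPS)}


@dataclass
class GraphBatch:
    """Dense node-padded batch of subject graphs (one or T snapshots)."""

    X: list[np.ndarray]            # T x [B, N, d] (T = 1 for static models)
    A: list[np.ndarray]            # T x [B, N, N], nonnegative weights
    node_mask: np.ndarray          # [B, N]
    labels: np.ndarray             # [B]
    subject_ids: list[str]
    node_labels: list[list[str]]   # per graph

    @property
    def n_graphs(self) -> int:
        return self.node_mask.shape[0]

    def subset(self, idx: np.ndarray) -> "GraphBatch":
        return GraphBatch(
            X=[x[idx] for x in self.X],
            A=[a[idx] for a in self.A],
            node_mask=self.node_mask[idx],
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            node_labels=[self.node_labels[i] for i in idx],
        )


def batch_graphs(graphs: list[SubjectGraph] | list[list[SubjectGraph]]) -> GraphBatch:
    """Pad a list of graphs (or per-subject snapshot lists) into a batch."""
    snapshots = isinstance(graphs[0], list)
    per_subject = graphs if snapshots else [[g] for g in graphs]
    T = len(per_subject[0])
    if any(len(s) != T for s in per_subject):
        raise ValueError("all subjects must have the same number of snapshots")
    N = max(s[0].n_nodes for s in per_subject)
    d = per_subject[0][0].node_features.shape[1]
    B = len(per_subject)
    X = [np.zeros((B, N, d)) for _ in range(T)]
    A = [np.zeros((B, N, N)) for _ in range(T)]
    mask = np.zeros((B, N))
    labels, sids, nlabels = [], [], []
    for i, snaps in enumerate(per_subject):
        n = snaps[0].n_nodes
        mask[i, :n] = 1.0
        labels.append(LABEL_OF[snaps[0].group])
        sids.append(snaps[0].subject_id)
        nlabels.append(list(snaps[0].node_labels))
        for t, g in enumerate(snaps):
            if g.node_features.shape[1] != d:
                raise ValueError("feature dimensionality differs across graphs")
            X[t][i, :n] = g.node_features
            A[t][i, :n, :n] = np.abs(g.adjacency)
    return GraphBatch(X=X, A=A, node_mask=mask, labels=np.array(labels),
                      subject_ids=sids, node_labels=nlabels)


@dataclass
class FoldResult:
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    macro_f1: float
    per_class_recall: dict[str, float]
    confusion: np.ndarray
    model: object
    feature_stats: tuple[np.ndarray, np.ndarray]
    test_batch: GraphBatch


def evaluate_metrics(y_true, y_pred) -> dict:
    """Macro-F1 (absent classes count F1 = 0), per-class recall, confusion."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    labels = list(range(len(GROUPS)))
    return {
        "macro_f1": float(f1_score(y_true, y_pred, labels=labels,
                                   average="macro", zero_division=0)),
        "per_class_recall": {
            g.value: float(r)
            for g, r in zip(GROUPS, recall_score(y_true, y_pred, labels=labels,
                                                 average=None, zero_division=0))
        },
        "confusion": confusion_matrix(y_true, y_pred, labels=labels),
    }


def _zscore_stats(batch: GraphBatch) -> tuple[np.ndarray, np.ndarray]:
    rows = np.concatenate(
        [x[batch.node_mask > 0] for x in batch.X], axis=0
    )
    mu = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _apply_zscore(batch: GraphBatch, stats) -> GraphBatch:
    mu, sd = stats
    X = [((x - mu) / sd) * batch.node_mask[..., None] for x in batch.X]
    return GraphBatch(X=X, A=batch.A, node_mask=batch.node_mask,
                      labels=batch.labels, subject_ids=batch.subject_ids,
                      node_labels=batch.node_labels)


def _forward(model, batch: GraphBatch, spec: ModelSpec, training=False, rng=None):
    if spec.arch == ModelArch.STGNN:
        return model.forward(batch.X, batch.A, batch.node_mask, training, rng)
    return model.forward(batch.X[0], batch.A[0], batch.node_mask, training, rng)


class Ensemble:
    """A few independently initialized models; logits are averaged.

    Averaging over random initializations damps the optimization noise of
    training small graph networks on few subjects; attention tensors are
    likewise averaged across members when retrieved.
    """

    def __init__(self, members: list):
        self.members = members

    @property
    def params(self):
        return [p for m in self.members for p in m.params]


def _train_single(batch: GraphBatch, spec: ModelSpec, seed: int):
    rng_init = substream(seed, "model_init")
    rng_drop = substream(seed, "dropout")
    model = build_model(spec, batch.X[0].shape[-1], rng_init)
    opt = ad.Adam(model.params, lr=spec.lr)
    counts = np.bincount(batch.labels, minlength=3).astype(float)
    weights = np.where(counts > 0, batch.labels.size / (3.0 * np.maximum(counts, 1)), 0.0)
    best, stall = np.inf, 0
    for _ in range(spec.epochs):
        opt.zero_grad()
        logits = _forward(model, batch, spec, training=True, rng=rng_drop)
        loss = weighted_cross_entropy(logits, batch.labels, weights)
        loss.backward()
        opt.step()
        if loss.data < best - 1e-4:
            best, stall = float(loss.data), 0
        else:
            stall += 1
            if stall >= spec.patience:
                break
    return model


def train_model(batch: GraphBatch, spec: ModelSpec, seed: int):
    """Fit the model (an ensemble when ``spec.n_ensemble > 1``).

    Each member stops early when its training loss has not improved by
    more than 1e-4 for ``spec.patience`` consecutive epochs.
    """
    if spec.n_ensemble <= 1:
        return _train_single(batch, spec, seed)
    members = [
        _train_single(batch, spec, substream_seed(seed, f"member{i}"))
        for i in range(spec.n_ensemble)
    ]
    return Ensemble(members)


def model_logits(model, batch: GraphBatch, spec: ModelSpec) -> np.ndarray:
    if isinstance(model, Ensemble):
        return np.mean(
            [_forward(m, batch, spec, training=False).data for m in model.members],
            axis=0,
        )
    return _forward(model, batch, spec, training=False).data


def predict(model, batch: GraphBatch, spec: ModelSpec) -> np.ndarray:
    return np.argmax(model_logits(model, batch, spec), axis=-1)


def cross_validate(
    graphs: list[SubjectGraph] | list[list[SubjectGraph]],
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
) -> list[FoldResult]:
    """Stratified subject-independent k-fold cross-validation."""
    batch = batch_graphs(graphs)
    counts = np.bincount(batch.labels, minlength=3)
    for g, c in zip(GROUPS, counts):
        if 0 < c < k:
            raise ValueError(f"class {g.value} has {c} subjects < {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=substream_seed(seed, "folds"))
    results = []
    for fold_id, (tr, te) in enumerate(skf.split(np.zeros(batch.n_graphs), batch.labels)):
        train_b = batch.subset(tr)
        stats = _zscore_stats(train_b)
        train_z = _apply_zscore(train_b, stats)
        test_z = _apply_zscore(batch.subset(te), stats)
        model = train_model(train_z, spec, substream_seed(seed, f"fold{fold_id}"))
        y_pred = predict(model, test_z, spec)
        m = evaluate_metrics(test_z.labels, y_pred)
        results.append(FoldResult(
            fold_id=fold_id,
            train_ids=train_z.subject_ids,
            test_ids=test_z.subject_ids,
            y_true=test_z.labels,
            y_pred=y_pred,
            macro_f1=m["macro_f1"],
            per_class_recall=m["per_class_recall"],
            confusion=m["confusion"],
            model=model,
            feature_stats=stats,
            test_batch=test_z,
        ))
    return results


def pooled_metrics(results: list[FoldResult]) -> dict:
    """Metrics over predictions pooled across all test folds."""
    y_true = np.concatenate([r.y_true for r in results])
    y_pred = np.concatenate([r.y_pred for r in results])
    return evaluate_metrics(y_true, y_pred)
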