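"""Graph neural networks for subject-graph classification.

Three architectures over dense batched graphs (node-padded, masked):

* GCN — four stacked symmetric-degree-normalized graph convolutions
  (hidden 64, ReLU), global mean pooling, linear classifier.
* GAT — four stacked multi-head attention layers (4 heads, hidden 64,
  dropout 0.5); attention coefficients are retrievable per layer / head /
  edge for the explainability stage.
* STGNN — a graph convolution applied to each of T temporal snapshot
  graphs, a GRU cell carrying node state across snapshots, a final graph
  convolution, then pooling and classification.

Edge weights enter the convolutions as nonnegative |r|; attention logits
additionally receive log(w) so stronger edges attract more attention mass
before normalization. All parameters are initialized from a caller-owned
numpy Generator, so identical seeds give identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import ModelArch
from . import autodiff as ad
from .autodiff import Tensor

N_CLASSES = 3


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training configuration.

    ``dropout=None`` resolves per architecture: 0.5 for GAT and STGNN,
    none for the plain GCN (whose reference configuration specifies only
    depth and width).
    """

    arch: ModelArch = ModelArch.GAT
    n_layers: int = 4
    hidden: int = 64
    heads: int = 4
    dropout: float | None = None
    temporal_steps: int = 3
    lr: float = 5e-3
    epochs: int = 200
    patience: int = 40
    n_ensemble: int = 1  # >1: independently initialized members, logits averaged

    def __post_init__(self) -> None:
        if self.hidden <= 0 or self.heads < 1:
            raise ValueError("hidden must be positive and heads >= 1")
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")

    @property
    def dropout_rate(self) -> float:
        if self.dropout is not None:
            return self.dropout
        return 0.0 if self.arch == ModelArch.GCN else 0.5


def _glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


def _zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _dropout(h: Tensor, p: float, training: bool, rng) -> Tensor:
    if not training or p <= 0 or rng is None:
        return h
    keep = rng.random(h.shape) >= p
    return ad.mul(h, keep / (1.0 - p))


def _normalized_adjacency(A: Tensor, node_mask: np.ndarray) -> Tensor:
    """D^{-1/2} (A + I) D^{-1/2} with self-loops on real nodes only.

    Differentiable in A so that soft edge masks can flow gradients
    through the normalization.
    """
    m = node_mask[..., None] * node_mask[..., None, :]        # [B,N,N]
    eye = np.eye(A.shape[-1])[None] * node_mask[..., None] * node_mask[..., None, :]
    A_hat = ad.add(ad.mul(A, m), eye)
    deg = ad.tsum(A_hat, axis=-1, keepdims=True)              # [B,N,1]
    dinv = ad.power(ad.add(deg, 1e-12), -0.5)
    dinv = ad.mul(dinv, node_mask[..., None])
    return ad.mul(ad.mul(A_hat, dinv), ad.transpose(dinv, (0, 2, 1)))


def _masked_mean_pool(h: Tensor, node_mask: np.ndarray) -> Tensor:
    s = ad.tsum(ad.mul(h, node_mask[..., None]), axis=1)      # [B,F]
    counts = node_mask.sum(axis=1, keepdims=True)
    return ad.mul(s, 1.0 / np.maximum(counts, 1.0))


class GCN:
    """Stacked spectral-style graph convolutions with mean-pool readout."""

    def __init__(self, spec: ModelSpec, in_dim: int, rng: np.random.Generator):
        self.spec = spec
        dims = [in_dim] + [spec.hidden] * spec.n_layers
        self.W = [_glorot(rng, dims[i], dims[i + 1]) for i in range(spec.n_layers)]
        self.b = [_zeros(dims[i + 1]) for i in range(spec.n_layers)]
        self.W_out = _glorot(rng, spec.hidden, N_CLASSES)
        self.b_out = _zeros(N_CLASSES)

    @property
    def params(self) -> list[Tensor]:
        return [*self.W, *self.b, self.W_out, self.b_out]

    def forward(self, X, A, node_mask, training: bool = False, rng=None) -> Tensor:
        A_norm = _normalized_adjacency(ad.ensure(A), node_mask)
        h = ad.ensure(X)
        for W, b in zip(self.W, self.b):
            h = _dropout(h, self.spec.dropout_rate, training, rng)
            h = ad.relu(ad.add(ad.matmul(ad.matmul(A_norm, h), W), b))
        pooled = _masked_mean_pool(h, node_mask)
        return ad.add(ad.matmul(pooled, self.W_out), self.b_out)


class GAT:
    """Multi-head graph attention stack with retrievable coefficients."""

    def __init__(self, spec: ModelSpec, in_dim: int, rng: np.random.Generator):
        self.spec = spec
        per_head = spec.hidden // spec.heads
        dims = [in_dim] + [spec.hidden] * spec.n_layers
        self.W, self.a_src, self.a_dst = [], [], []
        for i in range(spec.n_layers):
            self.W.append(_glorot(rng, spec.heads, dims[i], per_head))
            self.a_src.append(_glorot(rng, spec.heads, per_head, 1))
            self.a_dst.append(_glorot(rng, spec.heads, per_head, 1))
        self.W_out = _glorot(rng, spec.hidden, N_CLASSES)
        self.b_out = _zeros(N_CLASSES)
        #: attention per layer from the most recent forward: [B, heads, N, N]
        self.last_attention: list[np.ndarray] = []

    @property
    def params(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst, self.W_out, self.b_out]

    def forward(self, X, A, node_mask, training: bool = False, rng=None) -> Tensor:
        A_t = ad.ensure(A)
        # neighbourhood mask: existing edges plus self-loops on real nodes
        m_pair = node_mask[:, :, None] * node_mask[:, None, :]
        eye = np.eye(A_t.shape[-1], dtype=bool)[None]
        attn_mask = ((A_t.data > 0) | eye) & (m_pair > 0)      # [B,N,N]
        # log edge weight biases the attention logits (self-loop weight 1)
        w = np.where(A_t.data > 0, A_t.data, 1.0)
        log_w = np.where(attn_mask, np.log(w), 0.0)[:, None]   # [B,1,N,N]

        spec = self.spec
        per_head = spec.hidden // spec.heads
        B, N = node_mask.shape
        h = ad.ensure(X)
        self.last_attention = []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            h = _dropout(h, spec.dropout_rate, training, rng)
            hb = ad.reshape(h, (B, 1, N, h.shape[-1]))
            z = ad.matmul(hb, W)                               # [B,H,N,F']
            s_src = ad.matmul(z, a_s)                          # [B,H,N,1]
            s_dst = ad.matmul(z, a_d)
            e = ad.add(s_src, ad.transpose(s_dst, (0, 1, 3, 2)))
            e = ad.add(ad.leaky_relu(e, 0.2), log_w)
            alpha = ad.masked_softmax(e, attn_mask[:, None], axis=-1)
            self.last_attention.append(alpha.data.copy())
            out = ad.matmul(alpha, z)                          # [B,H,N,F']
            out = ad.transpose(out, (0, 2, 1, 3))
            h = ad.elu(ad.reshape(out, (B, N, spec.heads * per_head)))
        pooled = _masked_mean_pool(h, node_mask)
        return ad.add(ad.matmul(pooled, self.W_out), self.b_out)


class _GRUCell:
    def __init__(self, dim: int, rng: np.random.Generator):
        self.Wz, self.Uz, self.bz = _glorot(rng, dim, dim), _glorot(rng, dim, dim), _zeros(dim)
        self.Wr, self.Ur, self.br = _glorot(rng, dim, dim), _glorot(rng, dim, dim), _zeros(dim)
        self.Wn, self.Un, self.bn = _glorot(rng, dim, dim), _glorot(rng, dim, dim), _zeros(dim)

    @property
    def params(self):
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                self.Wn, self.Un, self.bn]

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        z = ad.sigmoid(ad.add(ad.add(ad.matmul(x, self.Wz), ad.matmul(h, self.Uz)), self.bz))
        r = ad.sigmoid(ad.add(ad.add(ad.matmul(x, self.Wr), ad.matmul(h, self.Ur)), self.br))
        n = ad.tanh(ad.add(ad.add(ad.matmul(x, self.Wn), ad.matmul(ad.mul(r, h), self.Un)), self.bn))
        return ad.add(ad.mul(ad.add(1.0, ad.mul(z, -1.0)), n), ad.mul(z, h))


class STGNN:
    """Per-snapshot graph convolution + GRU temporal update + convolution."""

    def __init__(self, spec: ModelSpec, in_dim: int, rng: np.random.Generator):
        self.spec = spec
        self.W_in = _glorot(rng, in_dim, spec.hidden)
        self.b_in = _zeros(spec.hidden)
        self.gru = _GRUCell(spec.hidden, rng)
        self.W_sp = _glorot(rng, spec.hidden, spec.hidden)
        self.b_sp = _zeros(spec.hidden)
        self.W_out = _glorot(rng, spec.hidden, N_CLASSES)
        self.b_out = _zeros(N_CLASSES)

    @property
    def params(self) -> list[Tensor]:
        return [self.W_in, self.b_in, *self.gru.params, self.W_sp, self.b_sp,
                self.W_out, self.b_out]

    def forward(self, X_steps, A_steps, node_mask, training: bool = False, rng=None) -> Tensor:
        """``X_steps``/``A_steps`` are length-T lists of [B,N,d] / [B,N,N]."""
        h = Tensor(np.zeros((node_mask.shape[0], node_mask.shape[1], self.spec.hidden)))
        A_last = None
        for X_t, A_t in zip(X_steps, A_steps):
            A_norm = _normalized_adjacency(ad.ensure(A_t), node_mask)
            A_last = A_norm
            x = ad.relu(ad.add(ad.matmul(ad.matmul(A_norm, ad.ensure(X_t)), self.W_in), self.b_in))
            x = _dropout(x, self.spec.dropout_rate, training, rng)
            h = self.gru.step(x, h)
        h = ad.relu(ad.add(ad.matmul(ad.matmul(A_last, h), self.W_sp), self.b_sp))
        pooled = _masked_mean_pool(h, node_mask)
        return ad.add(ad.matmul(pooled, self.W_out), self.b_out)


def build_model(spec: ModelSpec, in_dim: int, rng: np.random.Generator):
    """Instantiate the requested architecture with deterministic init."""
    cls = {ModelArch.GCN: GCN, ModelArch.GAT: GAT, ModelArch.STGNN: STGNN}[spec.arch]
    return cls(spec, in_dim, rng)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           class_weights: np.ndarray) -> Tensor:
    """Mean cross-entropy with per-class weights (weighted average)."""
    onehot = np.eye(N_CLASSES)[labels]
    w = class_weights[labels][:, None]
    logp = ad.log_softmax(logits, axis=-1)
    weighted = ad.mul(ad.mul(logp, onehot), -w)
    return ad.mul(ad.tsum(weighted), 1.0 / w.sum())
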