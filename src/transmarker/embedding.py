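"""Unsupervised graph-attention embedding of state-specific networks.

A two-layer graph attention network (GAT) is trained per state: the first
layer uses multi-head attention with concatenated ELU outputs, the second a
single head projecting to the output dimension. Neighborhoods come from the
state's regulatory adjacency (symmetrized, with self-loops); the fused
structural similarity S(t) enters as a multiplicative weight on the
unnormalized attention coefficients. Training minimizes the binary
cross-entropy between sigmoid(E E^T) and the adjacency, with Adam and
patience-based early stopping; embeddings from the best-loss epoch are
returned.

Implemented directly in numpy with hand-derived gradients (dense masked
attention; the graphs here are a few thousand nodes at most). A finite-
difference check in the test suite guards the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._optim import Adam
from .network_construction import StateGraph
from .topology import StructuralMatrix

__all__ = [
    "GATConfig",
    "EmbeddingSet",
    "train_state_embedding",
    "reconstruct_adjacency",
    "reconstruction_loss",
]

_LEAKY_SLOPE = 0.2
_NEG_INF = -1e30
_CLAMP = 1e-7


@dataclass(frozen=True)
class GATConfig:
    hidden_units: int = 64
    heads_first_layer: int = 2
    output_dim: int = 62
    dropout: float = 0.1
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    patience: int = 50
    warmup_epochs: int = 100  # patience counting starts after the warm-up
    max_epochs: int = 1000
    seed: int = 0
    full_loss_max_nodes: int = 500  # above this, sample negatives per epoch

    def __post_init__(self):
        if min(self.hidden_units, self.heads_first_layer, self.output_dim,
               self.patience, self.max_epochs) <= 0:
            raise ValueError("GATConfig sizes must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EmbeddingSet:
    state_index: int
    E: np.ndarray
    final_loss: float
    epochs_run: int
    loss_curve: list[float] = field(default_factory=list)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _leaky(x):
    return np.where(x > 0, x, _LEAKY_SLOPE * x)


def _leaky_grad(x):
    return np.where(x > 0, 1.0, _LEAKY_SLOPE)


class _GATLayer:
    """One dense masked-attention layer with K heads (concatenated outputs).

    ``w_scale`` shrinks the Glorot init; the output layer uses a small scale
    so initial edge logits sit near zero (loss starts at ~n*log2) instead of
    deep in sigmoid saturation.
    """

    def __init__(self, rng, dim_in, dim_out, heads, w_scale=1.0):
        self.heads = heads
        lim_w = w_scale * np.sqrt(6.0 / (dim_in + dim_out))
        lim_a = np.sqrt(6.0 / (dim_out + 1))
        self.W = [rng.uniform(-lim_w, lim_w, (dim_in, dim_out)) for _ in range(heads)]
        self.a_src = [rng.uniform(-lim_a, lim_a, dim_out) for _ in range(heads)]
        self.a_dst = [rng.uniform(-lim_a, lim_a, dim_out) for _ in range(heads)]

    @property
    def params(self):
        return [*self.W, *self.a_src, *self.a_dst]

    def forward(self, h, mask, log_s, attn_drop=None):
        """Returns output (N, heads*dim_out) and a cache for backward."""
        outs, caches = [], []
        for k in range(self.heads):
            z = h @ self.W[k]
            s = z @ self.a_src[k]
            t = z @ self.a_dst[k]
            e = s[:, None] + t[None, :]
            l = _leaky(e)
            logits = np.where(mask, l + log_s, _NEG_INF)
            logits = logits - logits.max(axis=1, keepdims=True)
            ex = np.exp(logits) * mask
            alpha = ex / np.maximum(ex.sum(axis=1, keepdims=True), 1e-30)
            alpha_used = alpha if attn_drop is None else alpha * attn_drop[k]
            o = alpha_used @ z
            outs.append(_elu(o))
            caches.append((z, e, alpha, alpha_used, o))
        return np.concatenate(outs, axis=1), (h, caches)

    def backward(self, d_out, cache, mask, attn_drop=None):
        """Returns d_input and gradients aligned with ``params``."""
        h, caches = cache
        dim_out = self.W[0].shape[1]
        d_h = np.zeros_like(h)
        gW, gas, gad = [], [], []
        for k in range(self.heads):
            z, e, alpha, alpha_used, o = caches[k]
            d_o = d_out[:, k * dim_out:(k + 1) * dim_out] * _elu_grad(o)
            d_alpha_used = d_o @ z.T
            d_z = alpha_used.T @ d_o
            d_alpha = d_alpha_used if attn_drop is None else d_alpha_used * attn_drop[k]
            # masked-softmax backward (rows); alpha is 0 off-mask
            row_dot = (d_alpha * alpha).sum(axis=1, keepdims=True)
            d_logits = alpha * (d_alpha - row_dot)
            d_e = d_logits * _leaky_grad(e)
            d_s = d_e.sum(axis=1)
            d_t = d_e.sum(axis=0)
            d_z += d_s[:, None] * self.a_src[k][None, :]
            d_z += d_t[:, None] * self.a_dst[k][None, :]
            gas.append(z.T @ d_s)
            gad.append(z.T @ d_t)
            gW.append(h.T @ d_z)
            d_h += d_z @ self.W[k].T
        return d_h, [*gW, *gas, *gad]


class _GATModel:
    def __init__(self, rng, n_features, cfg: GATConfig):
        self.cfg = cfg
        self.layer1 = _GATLayer(rng, n_features, cfg.hidden_units,
                                cfg.heads_first_layer)
        self.layer2 = _GATLayer(
            rng, cfg.hidden_units * cfg.heads_first_layer, cfg.output_dim, 1,
            w_scale=0.02,
        )

    @property
    def params(self):
        return self.layer1.params + self.layer2.params

    def forward(self, x, mask, log_s, drop_masks=None):
        if drop_masks is None:
            x_in, c1in = x, None
            h1, cache1 = self.layer1.forward(x_in, mask, log_s)
            h1_in = h1
            e, cache2 = self.layer2.forward(h1_in, mask, log_s)
            return e, (c1in, cache1, None, cache2, x, h1)
        f1, a1, f2, a2 = drop_masks
        x_in = x * f1
        h1, cache1 = self.layer1.forward(x_in, mask, log_s, attn_drop=a1)
        h1_in = h1 * f2
        e, cache2 = self.layer2.forward(h1_in, mask, log_s, attn_drop=a2)
        return e, (f1, cache1, f2, cache2, x, h1)

    def backward(self, d_e, caches, mask, drop_masks=None):
        f1, cache1, f2, cache2, _x, _h1 = caches
        a1 = a2 = None
        if drop_masks is not None:
            _, a1, _, a2 = drop_masks
        d_h1_in, g2 = self.layer2.backward(d_e, cache2, mask, attn_drop=a2)
        d_h1 = d_h1_in if f2 is None else d_h1_in * f2
        _d_x, g1 = self.layer1.backward(d_h1, cache1, mask, attn_drop=a1)
        return g1 + g2


def reconstruct_adjacency(E: np.ndarray | EmbeddingSet) -> np.ndarray:
    """Edge likelihoods sigmoid(e_i . e_j); symmetric with entries in (0,1)."""
    emb = E.E if isinstance(E, EmbeddingSet) else np.asarray(E, dtype=float)
    if not np.all(np.isfinite(emb)):
        raise ValueError("embeddings contain non-finite entries")
    return expit(emb @ emb.T)


def reconstruction_loss(
    A: np.ndarray, A_hat: np.ndarray, entries: np.ndarray | None = None
) -> float:
    """Summed binary cross-entropy between adjacency and reconstruction.

    ``entries`` is an optional boolean matrix selecting the scored (i, j)
    pairs; by default every entry is scored. Predictions at exactly 0 or 1
    are clamped to [1e-7, 1 - 1e-7].
    """
    A = np.asarray(A, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    if A.shape != A_hat.shape:
        raise ValueError("shape mismatch between adjacency and reconstruction")
    p = np.clip(A_hat, _CLAMP, 1.0 - _CLAMP)
    bce = -(A * np.log(p) + (1.0 - A) * np.log(1.0 - p))
    if entries is not None:
        bce = bce[entries]
    return float(bce.sum())


def _bce_grad_logits(E, A, entries):
    """Gradient of the BCE (on scored entries) w.r.t. the embedding matrix."""
    p = expit(E @ E.T)
    g = np.where(entries, p - A, 0.0)
    loss = reconstruction_loss(A, p, entries)
    return loss, (g + g.T) @ E


def train_state_embedding(
    features: np.ndarray,
    structure: StructuralMatrix,
    adjacency: StateGraph,
    cfg: GATConfig,
) -> EmbeddingSet:
    """Train the per-state GAT and return best-epoch embeddings.

    ``features`` is the N x M node-feature matrix (rows aligned with the
    state graph's node list). Early stopping monitors the deterministic
    (dropout-free) reconstruction loss; training aborts on a non-finite loss.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    a_dir = adjacency.adjacency()
    if a_dir.sum() == 0:
        raise ValueError("state graph has no edges; attention neighborhoods undefined")
    if x.shape[0] != len(adjacency.nodes) or structure.S.shape != (n, n):
        raise ValueError("features/structure/adjacency sizes disagree")

    a_sym = np.clip(a_dir + a_dir.T, 0.0, 1.0)
    mask = (a_sym + np.eye(n)) > 0
    log_s = np.where(mask, np.log(structure.S + 1e-8), 0.0)
    target = a_sym  # reconstruction target: undirected edges, diag excluded
    off_diag = ~np.eye(n, dtype=bool)

    rng = np.random.default_rng(cfg.seed)
    model = _GATModel(rng, x.shape[1], cfg)
    opt = Adam(model.params, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)

    full_mode = n <= cfg.full_loss_max_nodes
    pos = (target > 0) & off_diag
    n_pos = int(pos.sum())

    def sample_entries():
        if full_mode:
            return off_diag
        neg_candidates = np.argwhere(off_diag & ~pos)
        take = rng.choice(len(neg_candidates), size=min(n_pos, len(neg_candidates)),
                         replace=False)
        sel = pos.copy()
        sel[tuple(neg_candidates[take].T)] = True
        return sel

    eval_entries = off_diag if full_mode else sample_entries()

    best_loss = np.inf
    best_e = None
    best_epoch = 0
    bad = 0
    curve: list[float] = []
    p_drop = cfg.dropout

    for epoch in range(cfg.max_epochs):
        if p_drop > 0:
            keep = 1.0 - p_drop
            drop_masks = (
                (rng.random(x.shape) < keep) / keep,
                [(rng.random((n, n)) < keep) / keep
                 for _ in range(cfg.heads_first_layer)],
                (rng.random((n, cfg.hidden_units * cfg.heads_first_layer)) < keep) / keep,
                [(rng.random((n, n)) < keep) / keep],
            )
        else:
            drop_masks = None
        entries = sample_entries()
        e_train, caches = model.forward(x, mask, log_s, drop_masks)
        loss_train, d_e = _bce_grad_logits(e_train, target, entries)
        if not np.isfinite(loss_train):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(state {adjacency.state_index})"
            )
        grads = model.backward(d_e, caches, mask, drop_masks)
        opt.step(grads)

        e_eval, _ = model.forward(x, mask, log_s, None)
        loss_eval = reconstruction_loss(
            target, reconstruct_adjacency(e_eval), eval_entries
        )
        curve.append(loss_eval)
        if loss_eval < best_loss - 1e-12:
            best_loss = loss_eval
            best_e = e_eval
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if epoch >= cfg.warmup_epochs and bad >= cfg.patience:
                break

    assert best_e is not None
    return EmbeddingSet(
        state_index=adjacency.state_index, E=best_e,
        final_loss=float(best_loss), epochs_run=best_epoch + 1,
        loss_curve=curve,
    )
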