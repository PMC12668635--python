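"""Multiclass disease-state classification on selected biomarker genes.

Cells from all states are stacked into one feature matrix restricted to the
biomarker genes (log1p library-normalized). A multilayer perceptron with
three ReLU hidden layers (128, 64, 32 units) and a softmax output is trained
with inverse-frequency class weights on a stratified 70/10/20 split; the
epoch with the best validation macro AUROC is kept, metrics are computed on
the held-out test set, and the whole procedure is repeated over seeds with
mean +/- std aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from ._optim import Adam
from ._utils import derive_seed, log1p_normalize

__all__ = [
    "ClassifierConfig",
    "ClassifierMetrics",
    "assemble_dataset",
    "compute_metrics",
    "class_weights",
    "train_and_evaluate",
]

_METRIC_NAMES = (
    "accuracy", "auroc", "auprc", "f1", "precision", "recall", "specificity",
)


@dataclass(frozen=True)
class ClassifierConfig:
    hidden: tuple[int, ...] = (128, 64, 32)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50
    n_runs: int = 50
    seed: int = 0


@dataclass
class ClassifierMetrics:
    mean: dict[str, float]
    std: dict[str, float]
    per_run: list[dict[str, float]] = field(default_factory=list)
    n_runs: int = 0
    seeds: list[int] = field(default_factory=list)

    def __str__(self) -> str:
        return ", ".join(
            f"{k}={self.mean[k]:.4f}±{self.std[k]:.4f}" for k in _METRIC_NAMES
        )


def assemble_dataset(
    counts_per_state: list[pd.DataFrame],
    dnb_genes: tuple[str, ...] | list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack cells from all states; features are DNB-gene log1p expression."""
    if len(dnb_genes) == 0:
        raise ValueError("empty biomarker gene set")
    if len(counts_per_state) < 2:
        raise ValueError("multiclass classification needs at least 2 states")
    blocks, labels = [], []
    for t, df in enumerate(counts_per_state):
        missing = [g for g in dnb_genes if g not in df.index]
        if missing:
            raise ValueError(f"biomarker genes missing from state {t}: {missing[:5]}")
        x = log1p_normalize(df.to_numpy(dtype=float))
        rows = [df.index.get_loc(g) for g in dnb_genes]
        blocks.append(x[rows].T)  # cells x genes
        labels.extend([t] * df.shape[1])
    return np.vstack(blocks), np.asarray(labels)


def class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights n_total / (k * n_c), indexed by class."""
    classes, counts = np.unique(y, return_counts=True)
    w = np.zeros(int(classes.max()) + 1)
    w[classes] = len(y) / (len(classes) * counts)
    return w


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict[str, float]:
    """Seven macro-averaged multiclass metrics from predicted probabilities."""
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = y_prob.shape[1]
    present = [c for c in range(n_classes) if np.any(y_true == c)]
    y_pred = y_prob.argmax(axis=1)

    onehot = np.zeros_like(y_prob)
    onehot[np.arange(len(y_true)), y_true] = 1.0
    aurocs, auprcs = [], []
    for c in present:
        if np.all(y_true == c):
            continue  # no negatives either: undefined
        aurocs.append(roc_auc_score(onehot[:, c], y_prob[:, c]))
        auprcs.append(average_precision_score(onehot[:, c], y_prob[:, c]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=list(range(n_classes)))
    specs = []
    for c in present:
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = cm.sum() - tp - fp - fn
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    return {
        "accuracy": float((y_pred == y_true).mean()),
        "auroc": float(np.mean(aurocs)) if aurocs else float("nan"),
        "auprc": float(np.mean(auprcs)) if auprcs else float("nan"),
        "f1": float(f1),
        "precision": float(prec),
        "recall": float(rec),
        "specificity": float(np.mean(specs)),
    }


class _MLP:
    def __init__(self, rng, n_in, hidden, n_out):
        dims = [n_in, *hidden, n_out]
        self.W, self.b = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            lim = np.sqrt(6.0 / (a + b))
            self.W.append(rng.uniform(-lim, lim, (a, b)))
            self.b.append(np.zeros(b))

    @property
    def params(self):
        return [*self.W, *self.b]

    def forward(self, x):
        acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            h = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
            acts.append(h)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, acts

    def backward(self, acts, probs, y_onehot, sample_w):
        n = len(y_onehot)
        delta = (probs - y_onehot) * sample_w[:, None] / n
        gW, gb = [], []
        for i in range(len(self.W) - 1, -1, -1):
            gW.insert(0, acts[i].T @ delta)
            gb.insert(0, delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return [*gW, *gb]


def _train_single(x_tr, y_tr, x_val, y_val, n_classes, cfg, seed):
    rng = np.random.default_rng(seed)
    model = _MLP(rng, x_tr.shape[1], cfg.hidden, n_classes)
    opt = Adam(model.params, lr=cfg.learning_rate)
    w = class_weights(np.concatenate([y_tr, y_val]))
    onehot = np.eye(n_classes)[y_tr]
    sample_w = w[y_tr]

    best_auroc, best_ce, best_params, bad = -np.inf, np.inf, None, 0
    n = len(y_tr)
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs, acts = model.forward(x_tr[idx])
            grads = model.backward(acts, probs, onehot[idx], sample_w[idx])
            opt.step(grads)
        val_probs, _ = model.forward(x_val)
        try:
            val_auroc = roc_auc_score(
                np.eye(n_classes)[y_val], val_probs, average="macro",
                multi_class="ovr",
            )
        except ValueError:
            val_auroc = 0.0
        val_ce = -float(np.mean(np.log(
            np.clip(val_probs[np.arange(len(y_val)), y_val], 1e-12, 1.0))))
        # AUROC is the stopping criterion; ties (AUROC saturates early on
        # separable data) break toward lower validation cross-entropy so the
        # restored weights are also calibrated for argmax decisions
        if val_auroc > best_auroc + 1e-12 or (
                val_auroc >= best_auroc - 1e-12 and val_ce < best_ce - 1e-12):
            improved_auroc = val_auroc > best_auroc + 1e-12
            best_auroc = max(best_auroc, val_auroc)
            best_ce = val_ce
            best_params = [p.copy() for p in model.params]
            if improved_auroc:
                bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return model


def train_and_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
) -> ClassifierMetrics:
    """Repeated stratified 70/10/20 train/val/test evaluation of the MLP."""
    cfg = cfg or ClassifierConfig()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("multiclass classification needs >= 2 classes")
    if counts.min() < 10:
        raise ValueError("each class needs at least 10 samples")
    n_classes = int(classes.max()) + 1

    runs, seeds = [], []
    for r in range(cfg.n_runs):
        seed = derive_seed(cfg.seed, "clf-run", r)
        seeds.append(seed)
        x_tmp, x_te, y_tmp, y_te = train_test_split(
            features, labels, test_size=0.2, stratify=labels, random_state=seed
        )
        x_tr, x_val, y_tr, y_val = train_test_split(
            x_tmp, y_tmp, test_size=0.125, stratify=y_tmp,
            random_state=derive_seed(seed, "val"),
        )
        model = _train_single(x_tr, y_tr, x_val, y_val, n_classes, cfg, seed)
        probs, _ = model.forward(x_te)
        runs.append(compute_metrics(y_te, probs))
    mean = {k: float(np.mean([r[k] for r in runs])) for k in _METRIC_NAMES}
    std = {k: float(np.std([r[k] for r in runs])) for k in _METRIC_NAMES}
    return ClassifierMetrics(mean=mean, std=std, per_run=runs,
                             n_runs=cfg.n_runs, seeds=seeds)
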