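"""Shared numerical helpers: seeding, normalization, small math utilities."""

from __future__ import annotations

import numpy as np

__all__ = [
    "derive_seed",
    "rng_from",
    "normalize_counts",
    "log1p_normalize",
    "zscore_rows",
    "row_normalize",
]

_SEED_MOD = 2**31 - 1


def derive_seed(base_seed: int, *labels) -> int:
    """Derive a stage-specific seed from a global seed and string/int labels.

    Deterministic, order-sensitive, and bounded below 2**31 so the result is
    usable anywhere a 32-bit seed is expected.
    """
    h = np.uint64(base_seed % _SEED_MOD)
    for lab in labels:
        for ch in str(lab).encode():
            h = np.uint64((int(h) * 1000003 + ch) % (2**61 - 1))
    return int(h) % _SEED_MOD


def rng_from(base_seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, *labels))


def normalize_counts(counts: np.ndarray, target: float | None = None) -> np.ndarray:
    """Library-size normalize a genes x cells count matrix.

    Each cell (column) is scaled to ``target`` total counts (default: the
    median library size across cells). Cells with zero total are left at zero.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if target is None:
        nz = lib[lib > 0]
        target = float(np.median(nz)) if nz.size else 1.0
    scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
    return counts * scale[None, :]


def log1p_normalize(counts: np.ndarray, target: float | None = None) -> np.ndarray:
    """log1p of library-size-normalized counts (the standard scRNA transform)."""
    return np.log1p(normalize_counts(counts, target=target))


def zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Center and scale each row to zero mean / unit variance.

    Constant rows are centered only. Applied to log-normalized expression
    before it enters the graph encoder, so embedding geometry reflects each
    gene's co-variation pattern across cells rather than its absolute level.
    """
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mu) / np.where(sd > 0, sd, 1.0)


def row_normalize(mat: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows are left as zero."""
    mat = np.asarray(mat, dtype=float)
    s = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, mat / s, 0.0)
    return out
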