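"""Fused local/global structural similarity matrices.

For each state graph two row-stochastic similarity profiles are built: a local
one from exponentially decayed shortest-path distances, and a global one from
pairwise products of PageRank scores. A convex combination with weight alpha
(default 0.3, favouring the global profile) yields the structural matrix S(t)
that weights attention during embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._utils import row_normalize
from .network_construction import StateGraph

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralMatrix",
    "local_similarity",
    "global_similarity",
    "combine_similarity",
    "structural_matrix",
]


@dataclass(frozen=True)
class StructuralMatrix:
    state_index: int
    S: np.ndarray
    S_local: np.ndarray
    S_global: np.ndarray
    alpha: float
    d_big: float


def local_similarity(graph: StateGraph, d_big: float | None = None) -> np.ndarray:
    """exp(-shortest_path) similarity on the undirected view, row-normalized.

    Disconnected pairs receive ``exp(-d_big)``; ``d_big`` defaults to the node
    count N (a finite surrogate for infinite distance that exceeds any
    achievable diameter).
    """
    n = len(graph.nodes)
    if d_big is None:
        d_big = float(n)
    g = graph.to_networkx().to_undirected()
    dist = np.full((n, n), d_big)
    idx = {v: i for i, v in enumerate(graph.nodes)}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = idx[src]
        for tgt, d in lengths.items():
            dist[i, idx[tgt]] = d
    raw = np.exp(-dist)
    return row_normalize(raw)


def global_similarity(
    graph: StateGraph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Row-normalized outer product of PageRank scores on the directed graph."""
    if not (0 < damping < 1):
        raise ValueError("damping must be in (0, 1)")
    g = graph.to_networkx()
    try:
        pr = nx.pagerank(g, alpha=damping, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:  # pragma: no cover
        raise RuntimeError(f"PageRank failed to converge: {exc}") from exc
    p = np.array([pr[v] for v in graph.nodes])
    return row_normalize(np.outer(p, p))


def combine_similarity(
    local: np.ndarray, global_: np.ndarray, alpha: float
) -> np.ndarray:
    """Entrywise convex combination alpha * local + (1 - alpha) * global."""
    if local.shape != global_.shape:
        raise ValueError(f"shape mismatch: {local.shape} vs {global_.shape}")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    return alpha * local + (1.0 - alpha) * global_


def structural_matrix(
    graph: StateGraph,
    alpha: float = 0.3,
    damping: float = 0.85,
    d_big: float | None = None,
) -> StructuralMatrix:
    loc = local_similarity(graph, d_big=d_big)
    glo = global_similarity(graph, damping=damping)
    s = combine_similarity(loc, glo, alpha)
    if np.any((loc.sum(axis=1) == 0) | (glo.sum(axis=1) == 0)):
        logger.warning("state %d: all-zero similarity row left as zero",
                       graph.state_index)
    return StructuralMatrix(
        state_index=graph.state_index, S=s, S_local=loc, S_global=glo,
        alpha=alpha, d_big=float(len(graph.nodes)) if d_big is None else d_big,
    )
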