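"""Cross-state alignment via entropic Gromov-Wasserstein optimal transport.

Consecutive states are compared through the pairwise Euclidean distance
matrices of their gene embeddings. The entropic GW problem

    min_G  sum_{ijkl} (D_ij - D'_kl)^2 G_ik G_jl  -  eps * H(G)
    s.t.   G 1 = p,  G^T 1 = q

is solved by projected gradient descent whose projection step is a log-domain
Sinkhorn (the standard Peyre-style scheme for the squared loss). Per-gene
structural-shift scores are the population standard deviations of the plan's
rows, summed over transitions into the cumulative alignment score R_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .embedding import EmbeddingSet

__all__ = [
    "DissimilarityMatrix",
    "TransportPlan",
    "AlignmentScores",
    "embedding_dissimilarity",
    "entropic_gw",
    "gw_cost",
    "transition_score",
    "cumulative_alignment_score",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    state_index: int
    D: np.ndarray

    def __post_init__(self):
        d = self.D
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("dissimilarity matrix must be symmetric, "
                             "nonnegative, zero-diagonal")


@dataclass(frozen=True)
class TransportPlan:
    transition: tuple[int, int]
    gamma: np.ndarray
    p: np.ndarray
    q: np.ndarray
    epsilon: float
    cost: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class AlignmentScores:
    genes: tuple[str, ...]
    per_transition: np.ndarray  # (T-1, N)
    cumulative: np.ndarray  # (N,)


def embedding_dissimilarity(E: EmbeddingSet | np.ndarray) -> DissimilarityMatrix:
    """Pairwise Euclidean distances between embedding rows."""
    emb = E.E if isinstance(E, EmbeddingSet) else np.asarray(E, dtype=float)
    state = E.state_index if isinstance(E, EmbeddingSet) else -1
    sq = (emb ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * emb @ emb.T
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DissimilarityMatrix(state_index=state, D=d)


def _lse_rows(m):
    mx = m.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(m - mx).sum(axis=1, keepdims=True))).ravel()


def _log_sinkhorn(cost, p, q, eps, tol=1e-9, max_iter=2000, f=None, g=None):
    """Log-domain Sinkhorn returning the coupling for the given cost matrix.

    ``f``/``g`` warm-start the dual potentials (used across the outer
    projected-gradient iterations, where the cost changes slowly). The
    marginal-violation check runs every few iterations to keep the inner
    loop cheap.
    """
    log_p = np.log(p)
    log_q = np.log(q)
    f = np.zeros_like(p) if f is None else f
    g = np.zeros_like(q) if g is None else g
    c_over = cost / eps
    for it in range(max_iter):
        f = eps * (log_p - _lse_rows(g[None, :] / eps - c_over))
        g = eps * (log_q - _lse_rows((f[:, None] / eps - c_over).T))
        if it % 5 == 4 or it == max_iter - 1:
            gamma = np.exp(f[:, None] / eps + g[None, :] / eps - c_over)
            if np.abs(gamma.sum(axis=1) - p).max() < tol:
                break
    gamma = np.exp(f[:, None] / eps + g[None, :] / eps - c_over)
    return gamma, f, g


def _round_to_polytope(gamma, p, q):
    """Project an almost-feasible coupling onto exact marginals.

    Scale-down rows, then columns, then distribute the leftover mass as a
    rank-one correction — nonnegativity is preserved and the change is of
    the order of the original marginal violation.
    """
    r = gamma.sum(axis=1)
    gamma = gamma * np.minimum(p / np.maximum(r, 1e-300), 1.0)[:, None]
    c = gamma.sum(axis=0)
    gamma = gamma * np.minimum(q / np.maximum(c, 1e-300), 1.0)[None, :]
    err_r = np.maximum(p - gamma.sum(axis=1), 0.0)
    err_c = np.maximum(q - gamma.sum(axis=0), 0.0)
    total = err_r.sum()
    if total > 0:
        gamma = gamma + np.outer(err_r, err_c) / total
    return np.maximum(gamma, 0.0)


def gw_cost(D: np.ndarray, Dprime: np.ndarray, gamma: np.ndarray) -> float:
    """Unregularized quadratic GW objective at a feasible coupling."""
    p = gamma.sum(axis=1)
    q = gamma.sum(axis=0)
    const = ((D ** 2) @ p)[:, None] + (q @ (Dprime ** 2).T)[None, :]
    tens = const - 2.0 * D @ gamma @ Dprime.T
    return float((tens * gamma).sum())


def entropic_gw(
    D: DissimilarityMatrix | np.ndarray,
    Dprime: DissimilarityMatrix | np.ndarray,
    p: np.ndarray | None = None,
    q: np.ndarray | None = None,
    epsilon: float = 1e-2,
    max_iter: int = 1000,
    tol: float = 1e-9,
    scale: bool = True,
    transition: tuple[int, int] = (-1, -1),
) -> TransportPlan:
    """Solve the entropic GW problem between two embedded states.

    Marginals default to uniform. When ``scale`` is on, both distance
    matrices are divided by the pooled median nonzero entry so that the
    default epsilon is comparable across datasets; the reported cost is
    evaluated on the scaled matrices.
    """
    d1 = D.D if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    d2 = Dprime.D if isinstance(Dprime, DissimilarityMatrix) else np.asarray(Dprime, float)
    n, m = d1.shape[0], d2.shape[0]
    p = np.full(n, 1.0 / n) if p is None else np.asarray(p, float)
    q = np.full(m, 1.0 / m) if q is None else np.asarray(q, float)
    if abs(p.sum() - 1) > 1e-8 or abs(q.sum() - 1) > 1e-8:
        raise ValueError("p and q must sum to 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    if scale:
        pooled = np.concatenate([d1[d1 > 0].ravel(), d2[d2 > 0].ravel()])
        med = float(np.median(pooled)) if pooled.size else 1.0
        if med > 0:
            d1 = d1 / med
            d2 = d2 / med

    const = ((d1 ** 2) @ p)[:, None] + (q @ (d2 ** 2).T)[None, :]
    gamma = np.outer(p, q)
    converged = False
    it = 0
    f = g = None
    # epsilon-scaling on the first projection: anneal the regularization down
    # to the target so the warm-started potentials enter the right basin fast
    eps_ladder = []
    e = max(epsilon, float(const.mean()))
    while e > epsilon * 1.001:
        eps_ladder.append(e)
        e /= 3.0
    tens = const - 2.0 * d1 @ gamma @ d2.T
    for e in eps_ladder:
        _, f, g = _log_sinkhorn(tens, p, q, e, tol=tol, max_iter=50, f=f, g=g)
    rel = float(np.abs(gamma).max())
    for it in range(1, max_iter + 1):
        tens = const - 2.0 * d1 @ gamma @ d2.T
        new, f, g = _log_sinkhorn(tens, p, q, epsilon, tol=tol, max_iter=200,
                                  f=f, g=g)
        delta = np.abs(new - gamma).max()
        gamma = new
        if delta < 1e-7 * max(rel, float(np.abs(gamma).max())):
            converged = True
            break
    # final polish: tighten the marginals at the converged cost tensor, then
    # round onto the transport polytope (exact marginals, tiny distortion)
    tens = const - 2.0 * d1 @ gamma @ d2.T
    gamma, f, g = _log_sinkhorn(tens, p, q, epsilon, tol=tol, max_iter=2000,
                                f=f, g=g)
    gamma = _round_to_polytope(gamma, p, q)
    cost = gw_cost(d1, d2, gamma)
    return TransportPlan(
        transition=transition, gamma=gamma, p=p, q=q, epsilon=epsilon,
        cost=cost, iterations=it, converged=converged,
    )


def transition_score(plan: TransportPlan) -> np.ndarray:
    """Per-gene score: population standard deviation of each plan row."""
    return plan.gamma.std(axis=1)


def cumulative_alignment_score(
    plans: list[TransportPlan], genes: tuple[str, ...] | list[str]
) -> AlignmentScores:
    """R_i = sum over transitions of the row-std transition scores."""
    if not plans:
        raise ValueError("need at least one transport plan")
    n = plans[0].gamma.shape[0]
    if any(pl.gamma.shape[0] != n for pl in plans):
        raise ValueError("transport plans have inconsistent sizes")
    if len(genes) != n:
        raise ValueError("gene list length does not match plan size")
    per = np.vstack([transition_score(pl) for pl in plans])
    return AlignmentScores(
        genes=tuple(genes), per_transition=per, cumulative=per.sum(axis=0)
    )
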