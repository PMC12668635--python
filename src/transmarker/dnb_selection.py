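"""Dynamic network biomarker selection.

Genes are ranked by cumulative alignment score, thresholded at the knee of
the descending score curve (kneedle criterion, with a top-fraction fallback),
assembled into connected components of the union network over states, and
each component is scored by the Dynamic Network Instability (DNI): the
population standard deviation over states of D(t) = exp((1 - rho_t) * Psi_t),
where rho_t is the component's undirected edge density and Psi_t the summed
per-gene alignment scores in state t. The component with maximal DNI is the
selected biomarker module C*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import AlignmentScores
from .network_construction import StateGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentReport",
    "kneedle_index",
    "elbow_select",
    "union_components",
    "score_component",
    "select_dnb",
]


@dataclass
class ComponentReport:
    component_id: int
    genes: tuple[str, ...]
    n_per_state: list[int] = field(default_factory=list)
    m_per_state: list[int] = field(default_factory=list)
    rho: list[float] = field(default_factory=list)
    psi: list[float] = field(default_factory=list)
    gcs: list[float] = field(default_factory=list)
    d: list[float] = field(default_factory=list)
    dni: float = 0.0
    rank: int | None = None
    singleton: bool = False


def kneedle_index(scores_desc: np.ndarray, sensitivity: float = 1.0) -> int | None:
    """Knee index of a descending convex-ish curve (kneedle criterion).

    Normalizes x and y to [0, 1], flips the curve to increasing-concave form,
    and returns the index maximizing the difference to the diagonal, provided
    that maximum survives the sensitivity cutoff. Returns None when no knee
    is detected (flat or strictly linear curves).
    """
    y = np.asarray(scores_desc, dtype=float)
    n = len(y)
    if n < 3 or y.max() == y.min():
        return None
    x_n = np.arange(n) / (n - 1)
    y_n = (y - y.min()) / (y.max() - y.min())
    diff = (1.0 - y_n) - x_n
    k = int(np.argmax(diff))
    if k in (0, n - 1):
        return None
    # kneedle threshold: local maximum must exceed the mean spacing-scaled cut
    t = diff[k] - sensitivity * np.abs(np.diff(x_n)).mean()
    if t <= 0:
        return None
    return k


def elbow_select(
    scores: AlignmentScores,
    fallback_fraction: float = 0.15,
    sensitivity: float = 1.0,
) -> tuple[str, ...]:
    """Select structurally variable genes above the knee of the score curve.

    Genes are sorted by cumulative score descending (ties broken by gene
    symbol for determinism). If no knee is found, or the knee keeps fewer
    than 3 or more than half of the genes, the top ``fallback_fraction``
    (rounded up) is taken instead.
    """
    if not (0 < fallback_fraction < 1):
        raise ValueError("fallback_fraction must be in (0, 1)")
    n = len(scores.genes)
    if n == 0:
        raise ValueError("empty score vector")
    order = sorted(range(n), key=lambda i: (-scores.cumulative[i], scores.genes[i]))
    sorted_scores = scores.cumulative[order]
    delta = kneedle_index(sorted_scores, sensitivity=sensitivity)
    if delta is None or delta < 3 or delta > n // 2:
        k = int(np.ceil(fallback_fraction * n))
        if delta is None:
            logger.info("no knee found; falling back to top %d genes", k)
        else:
            logger.info("knee at %d out of range; falling back to top %d", delta, k)
        delta = max(1, k)
    return tuple(scores.genes[i] for i in order[:delta])


def union_components(
    selected: tuple[str, ...] | set[str],
    graphs: list[StateGraph],
) -> list[ComponentReport]:
    """Connected components of the union network restricted to selected genes.

    The union takes every state's edges with both endpoints selected;
    components are found on the undirected view. Singleton components are
    retained and flagged.
    """
    sel = set(selected)
    nodes = set(graphs[0].nodes)
    if not sel <= nodes:
        raise ValueError(f"selected genes outside the node list: {sorted(sel - nodes)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(sorted(sel))
    for sg in graphs:
        for u, v in sg.edges:
            if u in sel and v in sel:
                g.add_edge(u, v)
    reports = []
    for cid, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    ):
        genes = tuple(sorted(comp))
        reports.append(
            ComponentReport(component_id=cid, genes=genes,
                            singleton=len(genes) == 1)
        )
    return reports


def score_component(
    report: ComponentReport,
    graphs: list[StateGraph],
    scores: AlignmentScores,
    psi_mode: str = "cumulative",
) -> ComponentReport:
    """Fill per-state density/cohesion/instability fields of a component.

    Per state t: n_t = |C|; m_t counts undirected edges within C (reciprocal
    directed edges collapse to one); rho_t = 2 m_t / (n_t (n_t - 1)), defined
    as 1 for singletons; Psi sums members' cumulative alignment scores R_i
    (the only per-gene quantity the alignment stage defines), so the state
    dependence of D_t = exp((1 - rho_t) * Psi) comes from the component's
    density trajectory weighted by its total alignment mass. DNI is the
    population standard deviation of the D_t series.

    ``psi_mode="per-transition"`` instead sums each state's outgoing
    transition scores (the final state reuses its incoming transition),
    making Psi itself state-dependent.
    """
    if psi_mode not in ("cumulative", "per-transition"):
        raise ValueError(f"unknown psi_mode {psi_mode!r}")
    gene_idx = {g: i for i, g in enumerate(scores.genes)}
    members = [gene_idx[g] for g in report.genes]
    n_states = len(graphs)
    n_transitions = scores.per_transition.shape[0]
    comp = set(report.genes)

    report.n_per_state, report.m_per_state = [], []
    report.rho, report.psi, report.gcs, report.d = [], [], [], []
    for t in range(n_states):
        n_t = len(comp)
        und = {frozenset((u, v)) for u, v in graphs[t].edges
               if u in comp and v in comp}
        m_t = len(und)
        rho = 1.0 if n_t == 1 else 2.0 * m_t / (n_t * (n_t - 1))
        if psi_mode == "cumulative":
            psi = float(scores.cumulative[members].sum())
        else:
            # state T has no outgoing transition; reuse the incoming one
            t_score = min(t, n_transitions - 1)
            psi = float(scores.per_transition[t_score, members].sum())
        gcs = (1.0 - rho) * (-psi)
        report.n_per_state.append(n_t)
        report.m_per_state.append(m_t)
        report.rho.append(rho)
        report.psi.append(psi)
        report.gcs.append(gcs)
        report.d.append(float(np.exp(-gcs)))
    report.dni = float(np.std(report.d))
    return report


def select_dnb(reports: list[ComponentReport]) -> ComponentReport:
    """Return the component with maximal DNI; assign ranks to all.

    Ties break toward the larger component, then the lexicographically
    smallest gene tuple.
    """
    if not reports:
        raise ValueError("no components to select from")
    ordered = sorted(
        reports, key=lambda r: (-r.dni, -len(r.genes), r.genes)
    )
    for rank, r in enumerate(ordered, start=1):
        r.rank = rank
    return ordered[0]
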