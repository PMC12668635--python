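"""State-specific regulatory network construction.

Differentially expressed genes are called per state against a reference
condition (|log2FC| and rank-sum p-value thresholds), the combined gene set is
mapped onto a prior directed regulatory network, and the resulting background
network is pruned per state with a path-consistency procedure based on
(conditional) mutual information under Gaussian estimators, yielding one
directed state graph per disease state over a shared node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import log1p_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "PriorNetwork",
    "StateGraph",
    "identify_degs",
    "assemble_background",
    "pc_cmi_prune",
    "gaussian_mi",
    "gaussian_cmi",
]


@dataclass(frozen=True)
class PriorNetwork:
    """Directed prior regulatory edges (source, target) with a provenance tag."""

    edges: tuple[tuple[str, str], ...]
    provenance: str = "prior"

    def __post_init__(self):
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate directed edges in prior network")
        for u, v in self.edges:
            if not u or not v:
                raise ValueError("empty gene symbol in prior network")

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None) -> "PriorNetwork":
        df = pd.read_csv(path, sep="\t")
        if not {"source", "target"} <= set(df.columns):
            raise ValueError("prior network TSV needs 'source' and 'target' columns")
        edges = tuple(dict.fromkeys(zip(df["source"].astype(str), df["target"].astype(str))))
        return cls(edges=edges, provenance=provenance or str(path))


@dataclass(frozen=True)
class StateGraph:
    """Directed gene network for one disease state over the shared node list."""

    state_index: int
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def adjacency(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.nodes)}
        a = np.zeros((len(self.nodes), len(self.nodes)))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
        return a

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def identify_degs(
    state_counts: pd.DataFrame,
    normal_counts: pd.DataFrame,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    pseudocount: float = 1.0,
) -> set[str]:
    """Call DEGs between a disease state and the reference condition.

    A gene is kept when |log2((mean_state + c) / (mean_ref + c))| is strictly
    above ``lfc_min`` (means of library-size-normalized counts, pseudocount c)
    and the two-sided Wilcoxon rank-sum p-value on log1p-normalized values is
    strictly below ``p_max``. Genes with missing or constant expression in
    either condition are excluded first.
    """
    if lfc_min <= 0 or not (0 < p_max < 1):
        raise ValueError("need lfc_min > 0 and 0 < p_max < 1")
    if not state_counts.index.equals(normal_counts.index):
        raise ValueError("gene indices of the two conditions differ")
    if state_counts.shape[1] < 2 or normal_counts.shape[1] < 2:
        raise ValueError("each condition needs at least 2 cells")

    xs = log1p_normalize(state_counts.to_numpy())
    xn = log1p_normalize(normal_counts.to_numpy())
    # fold changes on the library-normalized scale
    mean_s = _norm_means(state_counts)
    mean_n = _norm_means(normal_counts)

    degs: set[str] = set()
    for i, gene in enumerate(state_counts.index):
        a, b = xs[i], xn[i]
        if np.all(a == a[0]) or np.all(b == b[0]):
            continue  # constant expression in one condition
        lfc = np.log2((mean_s[i] + pseudocount) / (mean_n[i] + pseudocount))
        if abs(lfc) <= lfc_min:
            continue
        p = stats.ranksums(a, b).pvalue
        if p < p_max:
            degs.add(str(gene))
    return degs


def _norm_means(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    nz = lib[lib > 0]
    target = float(np.median(nz)) if nz.size else 1.0
    scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
    return (x * scale[None, :]).mean(axis=1)


def assemble_background(
    deg_union: set[str],
    pathway_genes: set[str],
    prior: PriorNetwork,
) -> nx.DiGraph:
    """Induce the prior network on the combined DEG + pathway gene set.

    Mapped genes without incident prior edges are retained as isolated nodes.
    """
    if not prior.edges:
        raise ValueError("prior network is empty")
    keep = set(deg_union) | set(pathway_genes)
    prior_genes = {g for e in prior.edges for g in e}
    mapped = keep & prior_genes
    g = nx.DiGraph()
    g.add_nodes_from(sorted(mapped))
    g.add_edges_from((u, v) for u, v in prior.edges if u in keep and v in keep)
    if g.number_of_edges() == 0:
        logger.warning(
            "combined gene set induces no edges on the prior network "
            "(%d mapped genes)", len(mapped)
        )
    logger.info(
        "background network: %d genes, %d directed edges",
        g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian mutual information MI(X,Y) = -1/2 log(1 - corr^2)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    r2 = min(r * r, 1.0 - 1e-12)
    return -0.5 * float(np.log1p(-r2))


def gaussian_cmi(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Gaussian conditional MI via covariance determinants.

    CMI(X,Y|Z) = 1/2 log(|Sigma_XZ| |Sigma_YZ| / (|Sigma_Z| |Sigma_XYZ|)).
    Raises ``np.linalg.LinAlgError``-like ValueError on a singular covariance.
    """
    xz = np.cov(np.vstack([x, z]))
    yz = np.cov(np.vstack([y, z]))
    zz = np.cov(z) if z.ndim == 1 else np.cov(z)
    xyz = np.cov(np.vstack([x, y, z]))
    det_z = float(zz) if np.ndim(zz) == 0 else float(np.linalg.det(zz))
    d_xz, d_yz, d_xyz = (float(np.linalg.det(m)) for m in (xz, yz, xyz))
    if min(d_xz, d_yz, d_xyz) <= 0 or det_z <= 0:
        raise ValueError("singular covariance in conditional MI")
    return 0.5 * float(np.log(d_xz * d_yz / (det_z * d_xyz)))


def pc_cmi_prune(
    background: nx.DiGraph,
    state_counts: pd.DataFrame,
    max_order: int = 1,
    cmi_threshold: float = 0.03,
    state_index: int = 0,
) -> StateGraph:
    """Prune the background network with a path-consistency MI procedure.

    Order 0 removes edges whose Gaussian mutual information (on log1p
    counts) is at or below ``cmi_threshold``. Order 1 removes surviving
    edges (u, v) when the MAXIMAL conditional MI over single common
    neighbors z is at or below the threshold — the conservative
    path-consistency-CMI rule: an edge survives if at least one conditioning
    leaves measurable dependence. Edge direction is inherited from the
    background network; singular conditional tests are treated as
    non-informative (edge retained).
    """
    if max_order not in (0, 1):
        raise ValueError("max_order must be 0 or 1")
    if cmi_threshold <= 0:
        raise ValueError("cmi_threshold must be positive")
    missing = [n for n in background.nodes if n not in state_counts.index]
    if missing:
        raise ValueError(f"background nodes missing from expression: {missing[:5]}")

    nodes = tuple(sorted(background.nodes))
    # plain log1p: per-cell library scaling is compositionally biased on
    # small panels and subtracts shared regulon variation (the signal)
    expr = np.log1p(state_counts.loc[list(nodes)].to_numpy(dtype=float))
    row = {g: i for i, g in enumerate(nodes)}

    surviving = []
    for u, v in background.edges:
        mi = gaussian_mi(expr[row[u]], expr[row[v]])
        if mi > cmi_threshold:
            surviving.append((u, v))

    if max_order >= 1:
        und = nx.Graph()
        und.add_nodes_from(nodes)
        und.add_edges_from(surviving)
        kept = []
        for u, v in surviving:
            common = (set(und.neighbors(u)) & set(und.neighbors(v))) - {u, v}
            max_cmi = -np.inf
            for z in common:
                try:
                    c = gaussian_cmi(expr[row[u]], expr[row[v]], expr[row[z]])
                except ValueError:
                    logger.debug("singular covariance for (%s,%s|%s); edge kept", u, v, z)
                    continue
                max_cmi = max(max_cmi, c)
            if common and np.isfinite(max_cmi) and max_cmi <= cmi_threshold:
                continue
            kept.append((u, v))
        surviving = kept

    return StateGraph(state_index=state_index, nodes=nodes,
                      edges=frozenset(surviving))
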