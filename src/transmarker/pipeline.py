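"""End-to-end orchestration: networks -> topology -> embeddings -> alignment
-> biomarker selection -> classification.

The pipeline can run fully in memory (from a :class:`SimulatedDataset` or a
list of per-state count DataFrames plus a prior network) or from files via a
:class:`PipelineConfig`. Every stage derives its own seed from the global one
and a run directory, when given, receives TSV/CSV/JSON artifacts for each
stage plus a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import derive_seed, log1p_normalize, zscore_rows
from .alignment import (
    AlignmentScores,
    TransportPlan,
    cumulative_alignment_score,
    embedding_dissimilarity,
    entropic_gw,
)
from .classification import ClassifierMetrics, assemble_dataset, train_and_evaluate
from .config import PipelineConfig
from .dnb_selection import (
    ComponentReport,
    elbow_select,
    score_component,
    select_dnb,
    union_components,
)
from .embedding import EmbeddingSet, GATConfig, train_state_embedding
from .io import load_expression_dir, load_gene_list
from .network_construction import (
    PriorNetwork,
    StateGraph,
    assemble_background,
    identify_degs,
    pc_cmi_prune,
)
from .synthetic_data import SimulatedDataset
from .topology import StructuralMatrix, structural_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_from_matrices", "run_from_dataset", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    state_graphs: list[StateGraph]
    structures: list[StructuralMatrix]
    embeddings: list[EmbeddingSet]
    plans: list[TransportPlan]
    scores: AlignmentScores
    selected: tuple[str, ...]
    components: list[ComponentReport]
    dnb: ComponentReport
    metrics: ClassifierMetrics | None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def dnb_genes(self) -> tuple[str, ...]:
        return self.dnb.genes


def run_from_matrices(
    counts_per_state: list[pd.DataFrame],
    prior: PriorNetwork,
    cfg: PipelineConfig | None = None,
    pathway_genes: set[str] | None = None,
    normal_counts: pd.DataFrame | None = None,
    classify: bool = True,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory per-state count matrices.

    ``normal_counts`` is the optional DEG reference; without it every gene
    present in both the expression and the prior enters the background
    network.
    """
    cfg = cfg or PipelineConfig(states=[f"state{t+1}" for t in
                                        range(len(counts_per_state))])
    if len(cfg.states) != len(counts_per_state):
        cfg.states = [f"state{t+1}" for t in range(len(counts_per_state))]
    cfg.validate()
    timings: dict[str, float] = {}
    tic = time.perf_counter

    # --- stage 1: DEGs + background + per-state PC-CMI rewiring
    t0 = tic()
    if normal_counts is not None:
        deg_union: set[str] = set()
        for df in counts_per_state:
            deg_union |= identify_degs(df, normal_counts,
                                       lfc_min=cfg.lfc_min, p_max=cfg.p_max)
        logger.info("DEG union: %d genes", len(deg_union))
    else:
        deg_union = set(counts_per_state[0].index)
    background = assemble_background(deg_union, pathway_genes or set(), prior)
    in_expr = [g for g in background.nodes if g in counts_per_state[0].index]
    dropped = background.number_of_nodes() - len(in_expr)
    if dropped:
        logger.warning("%d background genes absent from expression; dropped", dropped)
        background = background.subgraph(in_expr).copy()
    if background.number_of_edges() == 0:
        raise RuntimeError("background network has no edges; pipeline cannot proceed")
    graphs = []
    for t, df in enumerate(counts_per_state):
        sg = pc_cmi_prune(background, df, max_order=cfg.cmi_max_order,
                          cmi_threshold=cfg.cmi_threshold, state_index=t)
        if not sg.edges:
            raise RuntimeError(f"state {t}: every edge pruned; "
                               "lower cmi_threshold or check the data")
        graphs.append(sg)
    timings["networks"] = tic() - t0

    # --- stage 2: structural similarity
    t0 = tic()
    structures = [structural_matrix(g, alpha=cfg.alpha,
                                    damping=cfg.pagerank_damping)
                  for g in graphs]
    timings["topology"] = tic() - t0

    # --- stage 3: per-state GAT embeddings
    t0 = tic()
    nodes = graphs[0].nodes
    embeddings = []
    for t, (g, s, df) in enumerate(zip(graphs, structures, counts_per_state)):
        feats = zscore_rows(np.log1p(df.loc[list(nodes)].to_numpy(dtype=float)))
        gcfg = GATConfig(**{**cfg.gat.__dict__,
                            "seed": derive_seed(cfg.seed, "gat", t)})
        embeddings.append(train_state_embedding(feats, s, g, gcfg))
    timings["embedding"] = tic() - t0

    # --- stage 4: GW alignment of consecutive states
    t0 = tic()
    plans = []
    for t in range(len(embeddings) - 1):
        d1 = embedding_dissimilarity(embeddings[t])
        d2 = embedding_dissimilarity(embeddings[t + 1])
        plan = entropic_gw(d1, d2, epsilon=cfg.epsilon, transition=(t, t + 1))
        if not plan.converged:
            logger.warning("GW transition %d->%d: max iterations reached", t, t + 1)
        plans.append(plan)
    scores = cumulative_alignment_score(plans, nodes)
    timings["alignment"] = tic() - t0

    # --- stage 5: knee selection, components, DNI ranking
    t0 = tic()
    selected = elbow_select(scores, fallback_fraction=cfg.fallback_fraction)
    components = union_components(selected, graphs)
    for rep in components:
        score_component(rep, graphs, scores)
    dnb = select_dnb(components)
    logger.info("DNB module: %d genes, DNI=%.4g", len(dnb.genes), dnb.dni)
    timings["selection"] = tic() - t0

    # --- stage 6: multiclass classification on DNB genes
    metrics = None
    if classify:
        t0 = tic()
        feats, labels = assemble_dataset(counts_per_state, dnb.genes)
        if cfg.append_pca_features > 0:
            feats = np.hstack([feats, _pca_features(counts_per_state,
                                                    cfg.append_pca_features)])
        ccfg = cfg.classifier.__class__(
            **{**cfg.classifier.__dict__,
               "seed": derive_seed(cfg.seed, "classifier")}
        )
        metrics = train_and_evaluate(feats, labels, ccfg)
        timings["classification"] = tic() - t0

    result = PipelineResult(
        config=cfg, state_graphs=graphs, structures=structures,
        embeddings=embeddings, plans=plans, scores=scores, selected=selected,
        components=components, dnb=dnb, metrics=metrics, timings=timings,
    )
    if out_dir is not None:
        write_run_outputs(result, out_dir)
    return result


def _pca_features(counts_per_state, n_components):
    from sklearn.decomposition import PCA

    x = np.hstack([log1p_normalize(df.to_numpy(dtype=float))
                   for df in counts_per_state]).T
    n_components = min(n_components, min(x.shape) - 1)
    return PCA(n_components=n_components, random_state=0).fit_transform(x)


def run_from_dataset(
    dataset: SimulatedDataset,
    cfg: PipelineConfig | None = None,
    classify: bool = True,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run on a simulated dataset, using the ground-truth union network as prior."""
    counts = [
        pd.DataFrame(mat, index=list(dataset.genes),
                     columns=[f"{name}_c{j}" for j in range(mat.shape[1])])
        for name, mat in zip(dataset.state_names, dataset.counts)
    ]
    prior = PriorNetwork(edges=tuple(sorted(dataset.grn.union_edges)),
                         provenance="simulated-grn-union")
    if cfg is not None and not cfg.states:
        cfg.states = list(dataset.state_names)
    return run_from_matrices(counts, prior, cfg=cfg, classify=classify,
                             out_dir=out_dir)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-driven entry point: loads expression, prior and pathway genes."""
    cfg.validate(require_paths=True)
    mats = load_expression_dir(cfg.expr_dir, cfg.states)
    prior = PriorNetwork.from_tsv(cfg.prior_path)
    pathway = load_gene_list(cfg.pathway_path) if cfg.pathway_path else set()
    normal = None
    state_mats = mats
    if cfg.normal_state is not None:
        normal = mats[cfg.states.index(cfg.normal_state)]
    return run_from_matrices(state_mats, prior, cfg=cfg, pathway_genes=pathway,
                             normal_counts=normal, out_dir=cfg.out_dir)


def write_run_outputs(result: PipelineResult, out_dir) -> None:
    """Persist every stage's artifacts plus a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = list(result.state_graphs[0].nodes)

    (out / "networks").mkdir(exist_ok=True)
    for g in result.state_graphs:
        pd.DataFrame(sorted(g.edges), columns=["source", "target"]).to_csv(
            out / "networks" / f"state{g.state_index}.edges.tsv",
            sep="\t", index=False,
        )
    (out / "networks" / "nodes.txt").write_text("\n".join(nodes) + "\n")

    (out / "embeddings").mkdir(exist_ok=True)
    for e in result.embeddings:
        df = pd.DataFrame(e.E, index=nodes)
        df.to_csv(out / "embeddings" / f"state{e.state_index}.tsv", sep="\t")

    (out / "plans").mkdir(exist_ok=True)
    for pl in result.plans:
        a, b = pl.transition
        pd.DataFrame(pl.gamma, index=nodes, columns=nodes).to_csv(
            out / "plans" / f"transition_{a}_{b}.csv"
        )

    sc = pd.DataFrame(result.scores.per_transition.T, index=nodes,
                      columns=[f"R_t{t}" for t in
                               range(result.scores.per_transition.shape[0])])
    sc["R_cumulative"] = result.scores.cumulative
    sc.index.name = "gene"
    sc.to_csv(out / "scores.tsv", sep="\t")

    (out / "selected.txt").write_text("\n".join(result.selected) + "\n")

    rows = []
    for rep in result.components:
        for gene in rep.genes:
            rows.append({"gene": gene, "component": rep.component_id,
                         "dni": rep.dni, "rank": rep.rank,
                         **{f"D_state{t}": d for t, d in enumerate(rep.d)}})
    pd.DataFrame(rows).to_csv(out / "components.tsv", sep="\t", index=False)

    dnb_edges = sorted({
        (u, v) for g in result.state_graphs for u, v in g.edges
        if u in result.dnb.genes and v in result.dnb.genes
    })
    pd.DataFrame(dnb_edges, columns=["source", "target"]).to_csv(
        out / "dnb_edges.tsv", sep="\t", index=False
    )
    (out / "dnb_genes.txt").write_text("\n".join(result.dnb.genes) + "\n")

    if result.metrics is not None:
        (out / "metrics.json").write_text(json.dumps(
            {"mean": result.metrics.mean, "std": result.metrics.std,
             "n_runs": result.metrics.n_runs}, indent=2))

    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "timings": result.timings,
        "n_genes": len(nodes),
        "n_states": len(result.state_graphs),
        "dnb_size": len(result.dnb.genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
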