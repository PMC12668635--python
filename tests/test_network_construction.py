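"""DEG calling, background assembly and PC-CMI pruning."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transmarker.network_construction import (
    PriorNetwork,
    assemble_background,
    gaussian_cmi,
    gaussian_mi,
    identify_degs,
    pc_cmi_prune,
)


def frames(a, b):
    genes = [f"g{i}" for i in range(a.shape[0])]
    return (pd.DataFrame(a, index=genes), pd.DataFrame(b, index=genes))


class TestIdentifyDegs:
    def test_constant_gene_excluded(self, rng):
        state = np.vstack([np.full(30, 7.0), rng.poisson(40, 30)])
        normal = np.vstack([np.full(30, 7.0), rng.poisson(5, 30)])
        s, n = frames(state, normal)
        assert "g0" not in identify_degs(s, n)

    def test_ninefold_change_included_with_ranksum_oracle(self, rng):
        # log2(9) ~ 3.17 > 1; rank-sum on clearly shifted samples is tiny
        state = np.vstack([rng.poisson(900, 50), rng.poisson(50, 50)])
        normal = np.vstack([rng.poisson(100, 50), rng.poisson(50, 50)])
        s, n = frames(state, normal)
        degs = identify_degs(s, n, pseudocount=1e-9)
        assert "g0" in degs and "g1" not in degs
        # oracle: the same rank-sum test scipy computes on the inputs
        from transmarker._utils import log1p_normalize

        p = stats.ranksums(log1p_normalize(s.to_numpy())[0],
                           log1p_normalize(n.to_numpy())[0]).pvalue
        assert p < 0.05

    def test_exact_twofold_is_excluded_by_strict_inequality(self):
        # log2FC exactly 1.0 fails the strict > 1.0 threshold
        rng = np.random.default_rng(1)
        base = rng.poisson(100, 200).astype(float)
        state = np.vstack([base * 2, base])
        normal = np.vstack([base, base])
        s, n = frames(state, normal)
        # pseudocount ~0 keeps the ratio exactly 2 on normalized means
        assert "g0" not in identify_degs(s, n, pseudocount=1e-12)

    def test_mismatched_index_and_tiny_condition_errors(self):
        a = pd.DataFrame(np.ones((2, 5)), index=["x", "y"])
        b = pd.DataFrame(np.ones((2, 5)), index=["x", "z"])
        with pytest.raises(ValueError):
            identify_degs(a, b)
        c = pd.DataFrame(np.ones((2, 1)), index=["x", "y"])
        with pytest.raises(ValueError):
            identify_degs(a, a.iloc[:, :1])
        del c


class TestAssembleBackground:
    PRIOR = PriorNetwork(edges=(("A", "B"), ("B", "C"), ("C", "D")))

    def test_disjoint_gene_set_gives_no_edges(self):
        g = assemble_background({"X", "Y"}, set(), self.PRIOR)
        assert g.number_of_edges() == 0

    def test_subgraph_induction(self):
        g = assemble_background({"A", "B", "C"}, set(), self.PRIOR)
        assert set(g.edges) == {("A", "B"), ("B", "C")}

    def test_pathway_genes_are_added(self):
        g = assemble_background({"A", "B"}, {"C"}, self.PRIOR)
        assert set(g.edges) == {("A", "B"), ("B", "C")}

    def test_empty_prior_errors(self):
        with pytest.raises(ValueError):
            assemble_background({"A"}, set(), PriorNetwork(edges=()))


class TestGaussianEstimators:
    def test_mi_closed_form_on_correlated_pair(self, rng):
        x = rng.normal(size=4000)
        y = 0.8 * x + 0.6 * rng.normal(size=4000)
        r = np.corrcoef(x, y)[0, 1]
        assert gaussian_mi(x, y) == pytest.approx(-0.5 * np.log(1 - r * r))

    def test_cmi_vanishes_given_the_mediator(self, rng):
        x = rng.normal(size=5000)
        z = x + 0.3 * rng.normal(size=5000)
        y = z + 0.3 * rng.normal(size=5000)  # x -> z -> y
        assert gaussian_cmi(x, y, z) < 0.02
        assert gaussian_mi(x, y) > 0.3


def _expr_frame(cols):
    genes = list(cols)
    return pd.DataFrame(np.vstack([cols[g] for g in genes]), index=genes)


class TestPcCmiPrune:
    def test_independent_pair_removed_and_coupled_pair_kept(self, rng):
        n = 500
        x = rng.poisson(50, n).astype(float)
        y = rng.poisson(50, n).astype(float)  # independent of x
        w = np.maximum(x + rng.normal(0, 2, n), 0)  # noisy copy of x
        counts = _expr_frame({"x": x, "y": y, "w": w})
        bg = nx.DiGraph([("x", "y"), ("x", "w")])
        sg = pc_cmi_prune(bg, counts, max_order=0)
        assert ("x", "y") not in sg.edges and ("x", "w") in sg.edges

    def test_chain_shortcut_removed_at_order_one(self, rng):
        n = 800
        a = rng.poisson(60, n).astype(float)
        b = np.maximum(a + rng.normal(0, 3, n), 0)
        c = np.maximum(b + rng.normal(0, 3, n), 0)  # c is a noisy copy of b
        counts = _expr_frame({"a": a, "b": b, "c": c})
        bg = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "c")])
        sg = pc_cmi_prune(bg, counts, max_order=1)
        assert ("a", "c") not in sg.edges
        assert {("a", "b"), ("b", "c")} <= set(sg.edges)

    def test_pruned_edges_subset_and_threshold_monotonicity(self, counts_frames,
                                                            dataset30):
        prior = PriorNetwork(edges=tuple(sorted(dataset30.grn.union_edges)))
        bg = assemble_background(set(dataset30.genes), set(), prior)
        lo = pc_cmi_prune(bg, counts_frames[0], cmi_threshold=0.01)
        hi = pc_cmi_prune(bg, counts_frames[0], cmi_threshold=0.1)
        assert lo.edges <= frozenset(bg.edges)
        assert hi.edges <= lo.edges  # raising the threshold never adds edges

    def test_precision_improves_over_unpruned_background(self, rng):
        # linear-Gaussian 30-gene system: retained edges should be enriched
        # for true edges relative to a background diluted with decoys
        n_genes, n_cells = 30, 300
        true_edges = [(f"g{i}", f"g{i + 1}") for i in range(0, 20, 2)]
        x = {}
        for i in range(n_genes):
            x[f"g{i}"] = rng.normal(50, 8, n_cells)
        for u, v in true_edges:
            x[v] = x[u] + rng.normal(0, 4, n_cells)
        counts = _expr_frame({g: np.maximum(x[g], 0) for g in x})
        decoys = [(f"g{i}", f"g{j}") for i, j in
                  rng.integers(0, n_genes, (40, 2)) if i != j
                  and (f"g{i}", f"g{j}") not in true_edges]
        bg = nx.DiGraph(true_edges + decoys)
        sg = pc_cmi_prune(bg, counts)
        retained = set(sg.edges)
        prec_bg = len(set(true_edges)) / bg.number_of_edges()
        prec = len(retained & set(true_edges)) / max(len(retained), 1)
        assert prec > prec_bg

    def test_missing_node_errors(self):
        counts = _expr_frame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            pc_cmi_prune(nx.DiGraph([("a", "zz")]), counts)
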