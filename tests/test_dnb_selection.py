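"""Knee selection, union components and DNI scoring."""

import numpy as np
import pytest

from conftest import make_graph
from transmarker.alignment import AlignmentScores
from transmarker.dnb_selection import (
    ComponentReport,
    elbow_select,
    kneedle_index,
    score_component,
    select_dnb,
    union_components,
)


def scores_from(values, genes=None, n_transitions=1):
    values = np.asarray(values, dtype=float)
    genes = genes or tuple(f"g{i}" for i in range(len(values)))
    per = np.tile(values / n_transitions, (n_transitions, 1))
    return AlignmentScores(genes=tuple(genes), per_transition=per,
                           cumulative=values)


class TestElbowSelect:
    def test_cliff_curve_selects_top_three(self):
        s = scores_from([10.0, 9.5, 9.0, 1.0, 0.9, 0.8])
        assert kneedle_index(np.array([10, 9.5, 9, 1, 0.9, 0.8])) == 3
        assert elbow_select(s) == ("g0", "g1", "g2")

    def test_all_equal_scores_fall_back_to_top_fraction(self):
        s = scores_from([1.0] * 100)
        sel = elbow_select(s, fallback_fraction=0.15)
        assert len(sel) == 15
        # tie-break on gene symbol: lexicographically first 15
        assert sel == tuple(sorted(s.genes)[:15])

    def test_single_gene_falls_back_to_itself(self):
        s = scores_from([3.0], genes=("only",))
        assert elbow_select(s) == ("only",)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            elbow_select(scores_from([1.0, 2.0]), fallback_fraction=1.5)


class TestUnionComponents:
    def test_no_induced_edges_gives_singletons(self):
        g = make_graph([("x", "y")], nodes=["a", "b", "x", "y"])
        reports = union_components(("a", "b"), [g])
        assert [r.genes for r in reports] == [("a",), ("b",)]
        assert all(r.singleton for r in reports)

    def test_union_semantics_across_states(self):
        g1 = make_graph([("A", "B")], nodes=["A", "B", "C"])
        g2 = make_graph([("B", "C")], nodes=["A", "B", "C"], state_index=1)
        reports = union_components(("A", "B", "C"), [g1, g2])
        assert [r.genes for r in reports] == [("A", "B", "C")]

    def test_matches_union_find_oracle(self, rng):
        nodes = [f"n{i}" for i in range(20)]
        graphs = []
        for t in range(3):
            pairs = rng.integers(0, 20, (12, 2))
            edges = [(nodes[i], nodes[j]) for i, j in pairs if i != j]
            graphs.append(make_graph(edges, nodes=nodes, state_index=t))
        selected = tuple(nodes[i] for i in rng.choice(20, 12, replace=False))

        parent = {g: g for g in selected}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for g in graphs:
            for u, v in g.edges:
                if u in parent and v in parent:
                    parent[find(u)] = find(v)
        oracle = {}
        for g in selected:
            oracle.setdefault(find(g), set()).add(g)
        got = {r.genes for r in union_components(selected, graphs)}
        assert got == {tuple(sorted(c)) for c in oracle.values()}

    def test_selected_outside_nodes_errors(self):
        g = make_graph([("a", "b")])
        with pytest.raises(ValueError):
            union_components(("zz",), [g])


def triangle_states(n_states=4):
    edges = [("A", "B"), ("B", "C"), ("A", "C")]
    return [make_graph(edges, state_index=t) for t in range(n_states)]


class TestScoreComponent:
    def test_fully_cohesive_invariant_module_has_zero_dni(self):
        graphs = triangle_states()
        scores = scores_from([0.2, 0.2, 0.2], genes=("A", "B", "C"),
                             n_transitions=3)
        rep = score_component(ComponentReport(0, ("A", "B", "C")), graphs,
                              scores)
        assert rep.rho == [1.0] * 4
        assert rep.gcs == [0.0] * 4
        assert rep.d == [1.0] * 4
        assert rep.dni == 0.0

    def test_hand_worked_three_gene_example(self):
        # n=3, m=2, Psi=0.6: rho=2/3, GCS=(1/3)(-0.6)=-0.2, D=exp(0.2)
        graphs = [make_graph([("A", "B"), ("B", "C")], state_index=t)
                  for t in range(2)]
        scores = scores_from([0.2, 0.2, 0.2], genes=("A", "B", "C"))
        rep = score_component(ComponentReport(0, ("A", "B", "C")), graphs,
                              scores)
        assert rep.rho[0] == pytest.approx(2 / 3)
        assert rep.gcs[0] == pytest.approx(-0.2)
        assert rep.d[0] == pytest.approx(np.exp(0.2), abs=1e-6)
        assert rep.d[0] == pytest.approx(1.22140, abs=1e-5)

    def test_dni_of_known_d_series(self):
        # D series (1.0, 1.0, 1.2214, 1.0): population std ~ 0.09587
        series = np.array([1.0, 1.0, np.exp(0.2), 1.0])
        assert np.std(series) == pytest.approx(0.09587, abs=1e-5)
        # reproduce through the scorer: state 2 edgeless, others triangles
        graphs = triangle_states(4)
        graphs[2] = make_graph([], nodes=["A", "B", "C"], state_index=2)
        per = np.full((3, 3), 0.2 / 9)  # cumulative R sums to Psi = 0.2
        scores = AlignmentScores(genes=("A", "B", "C"), per_transition=per,
                                 cumulative=per.sum(0))
        rep = score_component(ComponentReport(0, ("A", "B", "C")), graphs,
                              scores)
        np.testing.assert_allclose(rep.d, [1.0, 1.0, np.exp(0.2), 1.0],
                                   atol=1e-12)
        assert rep.dni == pytest.approx(0.09587, abs=1e-5)

    def test_reciprocal_directed_edges_count_once(self):
        g = make_graph([("A", "B"), ("B", "A")], state_index=0)
        scores = scores_from([0.1, 0.1], genes=("A", "B"))
        rep = score_component(ComponentReport(0, ("A", "B")), [g], scores)
        assert rep.m_per_state == [1]
        assert rep.rho[0] == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        edges = [("A", "B"), ("B", "C")]
        mapping = {"A": "Z9", "B": "M5", "C": "Q1"}
        g1 = [make_graph(edges, state_index=0),
              make_graph([("A", "B")], nodes=["A", "B", "C"], state_index=1)]
        g2 = [make_graph([(mapping[u], mapping[v]) for u, v in g.edges],
                         nodes=[mapping[v] for v in g.nodes],
                         state_index=g.state_index) for g in g1]
        vals = rng.random(3)
        s1 = scores_from(vals, genes=("A", "B", "C"))
        s2 = scores_from(vals, genes=tuple(mapping[g] for g in ("A", "B", "C")))
        r1 = score_component(ComponentReport(0, ("A", "B", "C")), g1, s1)
        r2 = score_component(
            ComponentReport(0, tuple(sorted(mapping.values()))), g2, s2)
        # relabeling genes does not change the DNI
        assert r1.dni == pytest.approx(r2.dni, abs=1e-12)


class TestSelectDnb:
    def _rep(self, cid, genes, dni):
        r = ComponentReport(cid, tuple(genes))
        r.dni = dni
        return r

    def test_single_component_returned(self):
        rep = self._rep(0, "ab", 0.5)
        assert select_dnb([rep]) is rep

    def test_argmax_by_dni(self):
        reports = [self._rep(0, "ab", 0.0), self._rep(1, "cd", 0.3),
                   self._rep(2, "ef", 0.1)]
        best = select_dnb(reports)
        assert best.component_id == 1
        assert [r.rank for r in reports] == [3, 1, 2]

    def test_tie_breaks_toward_larger_component(self):
        small = self._rep(0, ("a", "b", "c"), 0.2)
        large = self._rep(1, ("d", "e", "f", "g", "h"), 0.2)
        assert select_dnb([small, large]) is large

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_dnb([])
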