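"""Entropic Gromov-Wasserstein alignment and per-gene shift scores."""

import itertools

import numpy as np
import pytest

from transmarker.alignment import (
    TransportPlan,
    cumulative_alignment_score,
    embedding_dissimilarity,
    entropic_gw,
    gw_cost,
    transition_score,
)


def random_space(rng, n, d=4):
    return embedding_dissimilarity(rng.normal(size=(n, d)))


class TestDissimilarity:
    def test_identical_rows_give_zero(self):
        e = np.ones((3, 4))
        assert embedding_dissimilarity(e).D.max() == 0.0

    def test_three_four_five_triangle(self):
        e = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert embedding_dissimilarity(e).D[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        e = rng.normal(size=(7, 5))
        d = embedding_dissimilarity(e).D
        for i in range(7):
            for j in range(7):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(e[i] - e[j]), abs=1e-10)


class TestEntropicGw:
    def test_marginals_mass_and_nonnegativity(self, rng):
        for k in range(3):
            d1 = random_space(rng, 12)
            d2 = random_space(rng, 12)
            plan = entropic_gw(d1, d2, epsilon=1e-2)
            n = 12
            assert (plan.gamma >= 0).all()
            np.testing.assert_allclose(plan.gamma.sum(1), np.full(n, 1 / n),
                                       atol=1e-6)
            np.testing.assert_allclose(plan.gamma.sum(0), np.full(n, 1 / n),
                                       atol=1e-6)
            assert plan.gamma.sum() == pytest.approx(1.0, abs=1e-8)

    def test_self_alignment_cost_beats_independent_coupling(self, rng):
        d = random_space(rng, 10)
        plan = entropic_gw(d, d, epsilon=1e-2)
        p = np.full(10, 0.1)
        scaled = d.D / np.median(d.D[d.D > 0])
        indep = gw_cost(scaled, scaled, np.outer(p, p))
        assert plan.cost <= indep + 1e-9

    def test_entropy_dominated_limit_returns_product_coupling(self, rng):
        d1 = random_space(rng, 9)
        d2 = random_space(rng, 9)
        ms = float((d1.D ** 2).mean())
        plan = entropic_gw(d1, d2, epsilon=1e3 * ms, scale=False)
        np.testing.assert_allclose(plan.gamma, np.full((9, 9), 1 / 81),
                                   atol=1e-3)

    def test_three_point_exhaustive_permutation_oracle(self, rng):
        # solver cost must not exceed the best permutation coupling by more
        # than the entropy slack
        eps = 1e-2
        for _ in range(5):
            d1 = random_space(rng, 3)
            d2 = random_space(rng, 3)
            plan = entropic_gw(d1, d2, epsilon=eps, scale=False)
            best = np.inf
            for perm in itertools.permutations(range(3)):
                gamma = np.zeros((3, 3))
                for i, j in enumerate(perm):
                    gamma[i, j] = 1 / 3
                best = min(best, gw_cost(d1.D, d2.D, gamma))
            slack = eps * np.log(9)  # max entropy difference
            assert plan.cost <= best + slack + 1e-9

    def test_deterministic(self, rng):
        d1 = random_space(rng, 8)
        d2 = random_space(rng, 8)
        g1 = entropic_gw(d1, d2).gamma
        g2 = entropic_gw(d1, d2).gamma
        np.testing.assert_array_equal(g1, g2)

    def test_cost_increases_under_perturbation_on_average(self, rng):
        d = random_space(rng, 8)
        base = entropic_gw(d, d, epsilon=1e-2).cost
        costs = []
        for _ in range(20):
            noisy = d.D + np.abs(rng.normal(0, 0.05, d.D.shape))
            noisy = 0.5 * (noisy + noisy.T)
            np.fill_diagonal(noisy, 0.0)
            costs.append(entropic_gw(d.D, noisy, epsilon=1e-2).cost)
        assert base <= np.mean(costs)

    def test_invalid_marginals_error(self, rng):
        d = random_space(rng, 4)
        with pytest.raises(ValueError):
            entropic_gw(d, d, p=np.array([0.5, 0.5, 0.5, 0.5]))


def make_plan(gamma, transition=(0, 1)):
    return TransportPlan(transition=transition, gamma=gamma,
                         p=gamma.sum(1), q=gamma.sum(0), epsilon=1e-2,
                         cost=0.0, iterations=1, converged=True)


class TestScores:
    def test_uniform_plan_scores_zero(self):
        plan = make_plan(np.full((5, 5), 1 / 25))
        np.testing.assert_allclose(transition_score(plan), 0.0, atol=1e-15)

    def test_two_point_row_std(self):
        plan = make_plan(np.array([[0.5, 0.0], [0.0, 0.5]]))
        np.testing.assert_allclose(transition_score(plan), [0.25, 0.25])

    def test_permutation_rows_maximize_std_among_feasible_plans(self, rng):
        n = 6
        perm = np.eye(n) / n
        perm_std = transition_score(make_plan(perm)).mean()
        for _ in range(30):
            # random feasible plan: Sinkhorn-scale a positive matrix
            m = rng.random((n, n)) + 0.1
            for _ in range(200):
                m *= (1 / n) / m.sum(1, keepdims=True)
                m *= (1 / n) / m.sum(0, keepdims=True)
            assert transition_score(make_plan(m)).mean() <= perm_std + 1e-12

    def test_cumulative_is_sum_of_transitions(self, rng):
        genes = tuple("abcde")
        plans = [make_plan(np.full((5, 5), 1 / 25)),
                 make_plan(np.eye(5) / 5, (1, 2)),
                 make_plan(rng.dirichlet(np.ones(25)).reshape(5, 5), (2, 3))]
        scores = cumulative_alignment_score(plans, genes)
        manual = np.zeros(5)
        for pl in plans:
            for i in range(5):
                manual[i] += pl.gamma[i].std()
        np.testing.assert_allclose(scores.cumulative, manual, atol=1e-12)
        single = cumulative_alignment_score([plans[1]], genes)
        np.testing.assert_allclose(single.cumulative,
                                   transition_score(plans[1]))
        triple = cumulative_alignment_score([plans[1]] * 3, genes)
        np.testing.assert_allclose(triple.cumulative,
                                   3 * transition_score(plans[1]))

    def test_inconsistent_sizes_error(self):
        with pytest.raises(ValueError):
            cumulative_alignment_score(
                [make_plan(np.full((3, 3), 1 / 9)),
                 make_plan(np.full((4, 4), 1 / 16), (1, 2))], tuple("abc"))
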