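"""Genetic-programming engine: operators, selection pressure, evolution loop."""

from math import comb

import numpy as np
import pytest

from oscml import EvolutionConfig, evolve, subtree_crossover, subtree_mutation, tournament_select
from oscml.expressions import ExpressionTree, Node, parse_expression
from oscml.gp_engine import random_tree


class TestTournament:
    def test_full_tournament_returns_global_best(self):
        rng = np.random.default_rng(0)
        fitness = list(np.random.default_rng(1).uniform(size=30))
        pick = tournament_select(list(range(30)), 30, rng, fitness)
        assert fitness[pick] == max(fitness)

    def test_singleton_tournament_is_uniform(self):
        rng = np.random.default_rng(0)
        fitness = list(range(20))
        counts = np.zeros(20)
        for _ in range(4000):
            counts[tournament_select(list(range(20)), 1, rng, fitness)] += 1
        assert counts.min() > 0  # every rank reachable
        assert counts.max() / counts.min() < 2.5

    def test_selection_pressure_matches_exact_probability(self):
        """P(winner in top decile) for k=7 of 100 equals 1 - C(90,7)/C(100,7)."""
        rng = np.random.default_rng(5)
        fitness = list(range(100))  # rank i has fitness i
        top = bottom = 0
        n_draws = 10_000
        for _ in range(n_draws):
            w = tournament_select(list(range(100)), 7, rng, fitness)
            top += w >= 90
            bottom += w < 10
        p_top = 1 - comb(90, 7) / comb(100, 7)
        assert top / n_draws == pytest.approx(p_top, abs=0.02)
        assert top > bottom

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tournament_select([], 1, np.random.default_rng(0), [])


class TestCrossover:
    def _parents(self):
        p1 = parse_expression("max(a_low, min(b_low, c_low))", "fuzzy")
        p2 = parse_expression("dilator(concentrator(b_high))", "fuzzy")
        return p1, p2

    def test_root_swap_exchanges_parents(self):
        # with 1-node parents the only choice is the root
        p1 = ExpressionTree(Node(feature="a_low"), "fuzzy")
        p2 = ExpressionTree(Node(feature="b_high"), "fuzzy")
        c1, c2 = subtree_crossover(p1, p2, np.random.default_rng(0))
        assert c1.render() == "b_high"
        assert c2.render() == "a_low"

    def test_parents_unmodified(self):
        p1, p2 = self._parents()
        r1, r2 = p1.render(), p2.render()
        for seed in range(20):
            subtree_crossover(p1, p2, np.random.default_rng(seed))
        assert (p1.render(), p2.render()) == (r1, r2)

    def test_children_valid_and_within_cap(self):
        rng = np.random.default_rng(1)
        feats = ["a_low", "a_medium", "a_high", "b_low"]
        for _ in range(1000):
            p1 = ExpressionTree(random_tree("fuzzy", feats, 4, rng), "fuzzy")
            p2 = ExpressionTree(random_tree("fuzzy", feats, 4, rng), "fuzzy")
            c1, c2 = subtree_crossover(p1, p2, rng, depth_cap=6)
            c1.validate(max_depth=6)
            c2.validate(max_depth=6)

    def test_dialect_mismatch_rejected(self):
        p1 = ExpressionTree(Node(feature="Ax"), "arithmetic")
        p2 = ExpressionTree(Node(feature="Ax_low"), "fuzzy")
        with pytest.raises(ValueError, match="dialect"):
            subtree_crossover(p1, p2, np.random.default_rng(0))


class TestMutation:
    def test_children_valid_and_within_cap(self):
        rng = np.random.default_rng(2)
        feats = ["a_low", "b_low", "c_low"]
        for _ in range(1000):
            p = ExpressionTree(random_tree("fuzzy", feats, 5, rng), "fuzzy")
            child = subtree_mutation(p, feats, rng, depth_cap=6)
            child.validate(max_depth=6)

    def test_zero_budget_inserts_terminal(self):
        p = ExpressionTree(
            Node(op="dilator", children=[Node(op="dilator", children=[
                Node(op="dilator", children=[Node(feature="a_low")])])]), "fuzzy")
        # cap equal to current depth: any mutation at the deepest point must
        # be a terminal; whole-tree depth never grows
        for seed in range(50):
            child = subtree_mutation(p, ["a_low"], np.random.default_rng(seed),
                                     depth_cap=3)
            assert child.depth() <= 3


class TestEvolve:
    def test_separable_feature_reaches_perfect_training_auc(self, separable_toy):
        X, y = separable_toy
        model = evolve(X, y, EvolutionConfig(population_size=100, generations=20,
                                             seed=3))
        assert model.fitness == 1.0

    def test_fuzzy_dialect_reaches_perfect_training_auc(self, separable_fuzzy_toy):
        X, y = separable_fuzzy_toy
        model = evolve(X, y, EvolutionConfig(population_size=100, generations=20,
                                             seed=3), dialect="fuzzy")
        assert model.fitness == 1.0
        model.tree.validate(max_depth=6)

    def test_same_seed_reproduces_champion(self, separable_toy):
        X, y = separable_toy
        cfg = EvolutionConfig(population_size=60, generations=8, seed=9)
        a = evolve(X, y, cfg)
        b = evolve(X, y, cfg)
        assert a.expression == b.expression
        assert a.fitness == b.fitness

    def test_best_ever_fitness_is_non_decreasing(self, separable_toy):
        X, y = separable_toy
        model = evolve(X, y, EvolutionConfig(population_size=40, generations=10,
                                             seed=4))
        assert all(b >= a for a, b in zip(model.history, model.history[1:]))

    def test_single_class_labels_rejected(self, separable_toy):
        X, _ = separable_toy
        with pytest.raises(ValueError, match="single class"):
            evolve(X, np.zeros(len(X), dtype=int))

    def test_fuzzy_champion_uses_only_fuzzy_operators(self, separable_fuzzy_toy):
        X, y = separable_fuzzy_toy
        model = evolve(X, y, EvolutionConfig(population_size=60, generations=6,
                                             seed=5), dialect="fuzzy")
        model.tree.validate()  # raises if an arithmetic operator slipped in
        assert model.tree.dialect == "fuzzy"
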