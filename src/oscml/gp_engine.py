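"""Tree-based genetic programming for interpretable binary classifiers.

Individuals are expression trees (see :mod:`oscml.expressions`) in one of
two dialects: arithmetic trees scored through a sigmoid on z-scored
features, or fuzzy pattern trees evaluated directly on fuzzy memberships.
Evolution is generational: ramped half-and-half initialisation, tournament
selection, subtree crossover and subtree mutation, with the training AUC of
an individual's scores as its fitness.  The best individual ever seen is
tracked across generations (elitism of record) and returned with its
human-readable rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .expressions import (
    ARITHMETIC_OPS, FUZZY_OPS, R_CHOICES, ExpressionTree, Node,
)

__all__ = ["EvolutionConfig", "ExpressionModel", "evaluate_tree", "random_tree",
           "tournament_select", "subtree_crossover", "subtree_mutation", "evolve"]


@dataclass
class EvolutionConfig:
    """Knobs of the generational GP loop.

    ``init_depth`` is the ramped half-and-half range; ``depth_cap`` bounds
    every individual for interpretability.  Crossover/mutation probabilities
    follow classical GP practice.
    """

    population_size: int = 100
    generations: int = 20
    init_depth: tuple[int, int] = (2, 6)
    tournament_size: int = 7
    p_crossover: float = 0.9
    p_mutation: float = 0.1
    depth_cap: int = 6
    p_terminal_grow: float = 0.3
    p_constant: float = 0.2  # arithmetic dialect: chance a terminal is a constant
    seed: int = 7

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        lo, hi = self.init_depth
        if not (0 <= lo <= hi <= self.depth_cap):
            raise ValueError(f"init_depth {self.init_depth} incompatible with depth cap "
                             f"{self.depth_cap}")


@dataclass
class ExpressionModel:
    """An evolved classifier: the tree, its rendering and training fitness."""

    tree: ExpressionTree
    expression: str
    fitness: float
    generation: int = 0
    history: list[float] = field(default_factory=list)

    def score(self, table) -> np.ndarray:
        """Scores in [0, 1] for the rows of a DataFrame (or column dict)."""
        columns = _as_columns(table)
        return self.tree.score(columns)


def _as_columns(table) -> dict[str, np.ndarray]:
    if isinstance(table, dict):
        return table
    return {name: table[name].to_numpy(dtype=float) for name in table.columns}


def evaluate_tree(tree: ExpressionTree, record) -> np.ndarray:
    """Score rows of a feature record/table with a tree; values lie in [0,1]."""
    return tree.score(_as_columns(record))


# ---------------------------------------------------------------------------
# Random tree generation
# ---------------------------------------------------------------------------

def _random_terminal(dialect: str, features: list[str], rng: np.random.Generator,
                     p_constant: float) -> Node:
    if dialect == "arithmetic" and rng.random() < p_constant:
        return Node(value=float(np.round(rng.uniform(-1.0, 1.0), 3)))
    return Node(feature=features[rng.integers(len(features))])


def random_tree(dialect: str, features: list[str], depth: int,
                rng: np.random.Generator, method: str = "grow",
                p_terminal: float = 0.3, p_constant: float = 0.2) -> Node:
    """Generate a random subtree with the grow or full method.

    ``depth`` is the remaining depth budget; 0 forces a terminal.  WA/OWA
    weight slots are filled with constants from the admissible weight set.
    """
    ops = ARITHMETIC_OPS if dialect == "arithmetic" else FUZZY_OPS
    if depth <= 0 or (method == "grow" and rng.random() < p_terminal):
        return _random_terminal(dialect, features, rng, p_constant)
    names = list(ops)
    op = names[rng.integers(len(names))]
    n_args = ops[op]
    children = []
    for i in range(n_args):
        if op in ("WA", "OWA") and i == 2:
            children.append(Node(value=float(R_CHOICES[rng.integers(len(R_CHOICES))])))
        else:
            children.append(random_tree(dialect, features, depth - 1, rng, method,
                                        p_terminal, p_constant))
    return Node(op=op, children=children)


def _init_population(dialect: str, features: list[str], config: EvolutionConfig,
                     rng: np.random.Generator) -> list[ExpressionTree]:
    """Ramped half-and-half over the configured initial depth range."""
    lo, hi = config.init_depth
    depths = list(range(lo, hi + 1))
    pop = []
    for i in range(config.population_size):
        depth = depths[i % len(depths)]
        method = "grow" if (i // len(depths)) % 2 == 0 else "full"
        root = random_tree(dialect, features, depth, rng, method,
                           config.p_terminal_grow, config.p_constant)
        pop.append(ExpressionTree(root=root, dialect=dialect))
    return pop


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------

def tournament_select(population: list, k: int, rng: np.random.Generator,
                      fitness: list[float] | None = None):
    """Pick k individuals uniformly without replacement; return the fittest.

    ``population`` may be a list of ``(individual, fitness)`` pairs or a
    plain list with a parallel ``fitness`` list.  Ties go to the first
    sampled.
    """
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    if k > len(population):
        raise ValueError(f"tournament size {k} exceeds population size {len(population)}")
    idx = rng.choice(len(population), size=k, replace=False)
    fit = (lambda i: population[i][1]) if fitness is None else (lambda i: fitness[i])
    best = idx[0]
    for i in idx[1:]:
        if fit(i) > fit(best):
            best = i
    return population[best]


def subtree_crossover(parent1: ExpressionTree, parent2: ExpressionTree,
                      rng: np.random.Generator, depth_cap: int = 6
                      ) -> tuple[ExpressionTree, ExpressionTree]:
    """Swap subtrees rooted at independently chosen points of parent copies.

    A child exceeding the depth cap is replaced by a copy of its own parent,
    so the operator never produces an oversized individual.
    """
    if parent1.dialect != parent2.dialect:
        raise ValueError("crossover requires parents of the same dialect")
    c1, c2 = parent1.copy(), parent2.copy()
    nodes1, nodes2 = c1.root.nodes(), c2.root.nodes()
    n1 = nodes1[rng.integers(len(nodes1))]
    n2 = nodes2[rng.integers(len(nodes2))]
    sub1 = Node(op=n1.op, children=n1.children, feature=n1.feature, value=n1.value)
    sub2 = Node(op=n2.op, children=n2.children, feature=n2.feature, value=n2.value)
    n1.op, n1.children, n1.feature, n1.value = sub2.op, sub2.children, sub2.feature, sub2.value
    n2.op, n2.children, n2.feature, n2.value = sub1.op, sub1.children, sub1.feature, sub1.value
    if c1.depth() > depth_cap:
        c1 = parent1.copy()
    if c2.depth() > depth_cap:
        c2 = parent2.copy()
    return c1, c2


def subtree_mutation(parent: ExpressionTree, features: list[str],
                     rng: np.random.Generator, depth_cap: int = 6,
                     p_constant: float = 0.2) -> ExpressionTree:
    """Replace a uniformly chosen node by a grown random subtree.

    The replacement respects the remaining depth budget below the mutation
    point, so the child never exceeds the cap.
    """
    child = parent.copy()
    nodes = child.root.nodes()
    target = nodes[rng.integers(len(nodes))]
    # depth of the target below the root
    def depth_of(node: Node, goal: Node, d: int) -> int | None:
        if node is goal:
            return d
        for c in node.children:
            r = depth_of(c, goal, d + 1)
            if r is not None:
                return r
        return None

    d = depth_of(child.root, target, 0) or 0
    budget = max(depth_cap - d, 0)
    repl = random_tree(parent.dialect, features, budget, rng, "grow",
                       p_constant=p_constant)
    target.op, target.children, target.feature, target.value = (
        repl.op, repl.children, repl.feature, repl.value)
    return child


# ---------------------------------------------------------------------------
# Evolution loop
# ---------------------------------------------------------------------------

def _fitness(tree: ExpressionTree, columns: dict[str, np.ndarray],
             labels: np.ndarray) -> float:
    scores = tree.score(columns)
    if not np.all(np.isfinite(scores)) or np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(labels, scores))


def evolve(table, labels, config: EvolutionConfig | None = None,
           dialect: str = "arithmetic", features: list[str] | None = None
           ) -> ExpressionModel:
    """Evolve a classifier tree on a training table.

    Parameters
    ----------
    table : pandas.DataFrame or dict of column arrays
        Training features (z-scored for the arithmetic dialect, fuzzy
        memberships in [0, 1] for the fuzzy dialect).
    labels : array-like of {0, 1}
        Binary diagnosis labels; both classes must be present.
    config : EvolutionConfig
    dialect : {"arithmetic", "fuzzy"}
    features : list of str, optional
        Terminal set; defaults to the table's columns.

    Returns
    -------
    ExpressionModel
        Best-ever individual with its rendering and per-generation best
        fitness history.
    """
    config = config or EvolutionConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class; cannot evolve")
    columns = _as_columns(table)
    features = features if features is not None else list(columns)
    rng = np.random.default_rng(config.seed)

    population = _init_population(dialect, features, config, rng)
    fitness = [_fitness(t, columns, labels) for t in population]
    best_i = int(np.argmax(fitness))
    champion = population[best_i].copy()
    champ_fit = fitness[best_i]
    champ_gen = 0
    history = [champ_fit]

    for gen in range(1, config.generations + 1):
        new_pop: list[ExpressionTree] = []
        while len(new_pop) < config.population_size:
            p1 = tournament_select(population, config.tournament_size, rng, fitness)
            if rng.random() < config.p_crossover:
                p2 = tournament_select(population, config.tournament_size, rng, fitness)
                c1, c2 = subtree_crossover(p1, p2, rng, config.depth_cap)
            else:
                p2 = tournament_select(population, config.tournament_size, rng, fitness)
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if rng.random() < config.p_mutation:
                    child = subtree_mutation(child, features, rng, config.depth_cap,
                                             config.p_constant)
                if len(new_pop) < config.population_size:
                    new_pop.append(child)
        population = new_pop
        fitness = [_fitness(t, columns, labels) for t in population]
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > champ_fit:
            champ_fit = fitness[gen_best]
            champion = population[gen_best].copy()
            champ_gen = gen
        history.append(champ_fit)
        if champ_fit >= 1.0:
            break

    return ExpressionModel(tree=champion, expression=champion.render(),
                           fitness=champ_fit, generation=champ_gen, history=history)
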