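"""Grammatical evolution: integer-codon genomes mapped through a BNF grammar.

A genome is a sequence of 8-bit codons.  Genotype-to-phenotype mapping is a
leftmost derivation from the grammar's start symbol: whenever the leftmost
non-terminal has two or more productions, the next codon is consumed and the
production with index ``codon mod n`` is chosen (single-production rules
consume nothing).  The codon stream wraps around at the end, at most a fixed
number of times; if non-terminals remain when the budget is spent — or the
derivation exceeds the depth cap — the individual is *invalid*, which is a
value, not an error.

Two grammars ship with the package (``grammars/*.bnf``): an arithmetic one
producing add/sub/mul/div expressions over the 16 crisp features and decimal
constants, and a fuzzy one producing fuzzy-pattern-tree expressions over the
48 membership features.  Evolution is an ordinary genetic algorithm over
genomes: tournament selection, variable one-point crossover and per-codon
integer mutation, with training AUC of the mapped expression as fitness and
worst fitness for invalid individuals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .expressions import ExpressionTree, parse_expression
from .gp_engine import ExpressionModel, _as_columns, _fitness

__all__ = ["Grammar", "Genome", "GEConfig", "load_grammar", "bundled_grammar",
           "derive_phenotype", "map_genotype", "evolve_ge", "initial_invalid_fraction"]

logger = logging.getLogger(__name__)

_NT_RE = re.compile(r"<[^<>\s]+>")

#: fitness assigned to individuals whose genome fails to map
INVALID_FITNESS = -1.0


@dataclass(frozen=True)
class Grammar:
    """An ordered BNF grammar.

    ``rules`` maps each non-terminal to its ordered production list; a
    production is a tuple of tokens, each either ``("NT", name)`` or
    ``("T", text)``.  The start symbol is the left-hand side of the first
    rule.
    """

    rules: dict[str, list[tuple[tuple[str, str], ...]]]
    start: str

    def __post_init__(self) -> None:
        for nt, prods in self.rules.items():
            for prod in prods:
                for kind, val in prod:
                    if kind == "NT" and val not in self.rules:
                        raise ValueError(f"non-terminal <{val}> used in <{nt}> but never defined")
        # productivity: every non-terminal must be able to terminate
        productive: set[str] = set()
        changed = True
        while changed:
            changed = False
            for nt, prods in self.rules.items():
                if nt in productive:
                    continue
                for prod in prods:
                    if all(kind == "T" or val in productive for kind, val in prod):
                        productive.add(nt)
                        changed = True
                        break
        dead = set(self.rules) - productive
        if dead:
            raise ValueError(f"unproductive non-terminals (mapping can never terminate): "
                             f"{sorted(dead)}")


def _parse_production(text: str) -> tuple[tuple[str, str], ...]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    for m in _NT_RE.finditer(text):
        if m.start() > pos:
            tokens.append(("T", text[pos:m.start()]))
        tokens.append(("NT", m.group(0)[1:-1]))
        pos = m.end()
    if pos < len(text):
        tokens.append(("T", text[pos:]))
    return tuple(tokens)


def load_grammar(text: str) -> Grammar:
    """Parse BNF text: one rule per line, ``::=`` separator, ``|`` choices."""
    rules: dict[str, list] = {}
    start = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "::=" not in line:
            raise ValueError(f"malformed grammar line (no '::='): {line!r}")
        lhs, rhs = line.split("::=", 1)
        lhs = lhs.strip()
        if not (lhs.startswith("<") and lhs.endswith(">")):
            raise ValueError(f"rule left-hand side must be a <non-terminal>: {lhs!r}")
        name = lhs[1:-1]
        prods = [_parse_production(p.strip()) for p in rhs.split("|")]
        rules[name] = prods
        if start is None:
            start = name
    if start is None:
        raise ValueError("grammar has no rules")
    return Grammar(rules=rules, start=start)


def bundled_grammar(dialect: str) -> Grammar:
    """Load one of the two shipped grammars ("arithmetic" or "fuzzy")."""
    if dialect not in ("arithmetic", "fuzzy"):
        raise ValueError(f"no bundled grammar for dialect {dialect!r}")
    text = resources.files("oscml.grammars").joinpath(f"{dialect}.bnf").read_text()
    return load_grammar(text)


@dataclass(frozen=True)
class Genome:
    """Integer-codon genome with its wrapping budget."""

    codons: tuple[int, ...]
    wrap_limit: int = 3

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError("genome must have at least one codon")
        if self.wrap_limit < 1:
            raise ValueError("wrap limit must be >= 1")
        if any(c < 0 or c > 255 for c in self.codons):
            raise ValueError("codons must lie in [0, 255]")


def derive_phenotype(genome: Genome, grammar: Grammar,
                     depth_cap: int = 12) -> str | None:
    """Leftmost derivation of a genome into a phenotype string.

    Rules with >= 2 productions consume one codon and choose
    ``codon mod n``; the codon stream wraps at most ``wrap_limit`` times;
    derivations deeper than ``depth_cap``, or with non-terminals left when
    the codon budget is spent, yield ``None`` (invalid is a value).
    """
    budget = len(genome.codons) * genome.wrap_limit
    reads = 0
    out: list[str] = []
    stack: list[tuple[tuple[str, str], int]] = [(("NT", grammar.start), 0)]
    while stack:
        (kind, val), depth = stack.pop(0)
        if kind == "T":
            out.append(val)
            continue
        if depth > depth_cap:
            return None
        prods = grammar.rules[val]
        if len(prods) == 1:
            choice = 0
        else:
            if reads >= budget:
                return None
            codon = genome.codons[reads % len(genome.codons)]
            reads += 1
            choice = codon % len(prods)
        expansion = [((k, v), depth + 1) for (k, v) in prods[choice]]
        stack = expansion + stack
    return "".join(out)


def map_genotype(genome: Genome, grammar: Grammar, dialect: str = "arithmetic",
                 depth_cap: int = 12) -> ExpressionTree | None:
    """Map a genome through a grammar to a validated expression tree.

    Pure function of (genome, grammar): the derivation is
    :func:`derive_phenotype`; a phenotype that fails to derive or to parse
    under the dialect is invalid (``None``), never an exception.
    """
    phenotype = derive_phenotype(genome, grammar, depth_cap)
    if phenotype is None:
        return None
    try:
        return parse_expression(phenotype, dialect)
    except ValueError:
        return None


@dataclass
class GEConfig:
    """Knobs of the genetic algorithm over genomes."""

    population_size: int = 100
    generations: int = 20
    genome_length: int = 100
    wrap_limit: int = 3
    depth_cap: int = 12
    tournament_size: int = 7
    p_crossover: float = 0.9
    p_codon_mutation: float = 0.01
    seed: int = 7

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")


def _random_genome(config: GEConfig, rng: np.random.Generator) -> Genome:
    return Genome(tuple(int(c) for c in rng.integers(0, 256, size=config.genome_length)),
                  wrap_limit=config.wrap_limit)


def _ge_crossover(g1: Genome, g2: Genome, rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Variable one-point crossover: independent cut points in each parent."""
    c1 = int(rng.integers(1, len(g1.codons)))
    c2 = int(rng.integers(1, len(g2.codons)))
    child1 = g1.codons[:c1] + g2.codons[c2:]
    child2 = g2.codons[:c2] + g1.codons[c1:]
    return (Genome(child1, g1.wrap_limit), Genome(child2, g2.wrap_limit))


def _ge_mutate(g: Genome, p: float, rng: np.random.Generator) -> Genome:
    codons = list(g.codons)
    mask = rng.random(len(codons)) < p
    for i in np.flatnonzero(mask):
        codons[i] = int(rng.integers(0, 256))
    return Genome(tuple(codons), g.wrap_limit)


def initial_invalid_fraction(grammar: Grammar, config: GEConfig | None = None,
                             dialect: str = "arithmetic", n: int = 200,
                             seed: int = 0) -> float:
    """Fraction of random genomes that fail to map under a grammar."""
    config = config or GEConfig()
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n):
        g = _random_genome(config, rng)
        if map_genotype(g, grammar, dialect, config.depth_cap) is None:
            bad += 1
    return bad / n


def evolve_ge(table, labels, config: GEConfig | None = None,
              dialect: str = "arithmetic", grammar: Grammar | None = None
              ) -> ExpressionModel:
    """Evolve genomes with a GA; return the best-ever mapped phenotype.

    Fitness is the training AUC of the mapped expression's scores (invalid
    phenotypes get worst fitness).  Fully reproducible from ``config.seed``.
    """
    config = config or GEConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class; cannot evolve")
    grammar = grammar or bundled_grammar(dialect)
    columns = _as_columns(table)
    rng = np.random.default_rng(config.seed)

    population = [_random_genome(config, rng) for _ in range(config.population_size)]

    def assess(genome: Genome) -> tuple[float, ExpressionTree | None]:
        tree = map_genotype(genome, grammar, dialect, config.depth_cap)
        if tree is None:
            return INVALID_FITNESS, None
        # phenotypes referencing features absent from the table (e.g. ones
        # eliminated by feature selection) are invalid, not errors
        if not tree.root.terminals() <= set(columns):
            return INVALID_FITNESS, None
        return _fitness(tree, columns, labels), tree

    assessed = [assess(g) for g in population]
    invalid = sum(1 for f, _ in assessed if f == INVALID_FITNESS)
    logger.info("GE initial population: %d/%d invalid individuals (%.0f%%)",
                invalid, len(population), 100 * invalid / len(population))

    fitness = [f for f, _ in assessed]
    champion: ExpressionTree | None = None
    champ_fit = -np.inf
    champ_gen = 0
    history: list[float] = []

    def update_champion(gen: int) -> None:
        nonlocal champion, champ_fit, champ_gen
        best = int(np.argmax(fitness))
        if fitness[best] > champ_fit and assessed[best][1] is not None:
            champ_fit = fitness[best]
            champion = assessed[best][1]
            champ_gen = gen
        history.append(champ_fit)

    update_champion(0)
    for gen in range(1, config.generations + 1):
        new_pop: list[Genome] = []
        while len(new_pop) < config.population_size:
            i1 = _tournament(fitness, config.tournament_size, rng)
            i2 = _tournament(fitness, config.tournament_size, rng)
            p1, p2 = population[i1], population[i2]
            if rng.random() < config.p_crossover:
                c1, c2 = _ge_crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(new_pop) < config.population_size:
                    new_pop.append(_ge_mutate(child, config.p_codon_mutation, rng))
        population = new_pop
        assessed = [assess(g) for g in population]
        fitness = [f for f, _ in assessed]
        update_champion(gen)
        if champ_fit >= 1.0:
            break

    if champion is None:
        raise RuntimeError("every individual in every generation was invalid; "
                           "check the grammar/wrap settings")
    return ExpressionModel(tree=champion, expression=champion.render(),
                           fitness=float(champ_fit), generation=champ_gen,
                           history=history)


def _tournament(fitness: list[float], k: int, rng: np.random.Generator) -> int:
    idx = rng.choice(len(fitness), size=min(k, len(fitness)), replace=False)
    best = idx[0]
    for i in idx[1:]:
        if fitness[i] > fitness[best]:
            best = i
    return int(best)
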