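"""Expression trees shared by the genetic-programming and grammatical-evolution engines.

Two dialects exist:

* ``arithmetic`` — binary add/sub/mul and protected division over crisp
  (z-scored) features and numeric constants; a classifier score is obtained
  by passing the raw tree value through the logistic sigmoid.
* ``fuzzy`` — fuzzy-pattern-tree operators over fuzzy membership features:
  max, min, weighted average WA(a,b,r) = r*a + (1-r)*b, ordered weighted
  average OWA(a,b,r) = r*max(a,b) + (1-r)*min(a,b), and the unary dilator
  (square root) and concentrator (square).  These are closed on [0, 1], so
  the raw tree value is the score.

Trees render to, and parse from, a plain prefix notation such as
``OWA(concentrator(Rp_medium), Ax_medium, 0.6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node", "ExpressionTree", "parse_expression", "ARITHMETIC_OPS", "FUZZY_OPS",
    "sigmoid", "R_CHOICES",
]

#: operator name -> arity (WA/OWA take a third weight argument; see below)
ARITHMETIC_OPS: dict[str, int] = {"add": 2, "sub": 2, "mul": 2, "div": 2}
FUZZY_OPS: dict[str, int] = {"max": 2, "min": 2, "WA": 3, "OWA": 3,
                             "dilator": 1, "concentrator": 1}

#: admissible WA/OWA weight constants
R_CHOICES: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))

_PROTECTED_EPS = 1e-6


def sigmoid(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


@dataclass
class Node:
    """One tree node: an operator with children, a feature, or a constant."""

    op: str | None = None
    children: list["Node"] = field(default_factory=list)
    feature: str | None = None
    value: float | None = None

    @property
    def is_terminal(self) -> bool:
        return self.op is None

    def copy(self) -> "Node":
        return Node(op=self.op, children=[c.copy() for c in self.children],
                    feature=self.feature, value=self.value)

    def depth(self) -> int:
        if self.is_terminal:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def nodes(self) -> list["Node"]:
        """Pre-order list of all nodes (self first)."""
        out = [self]
        for c in self.children:
            out.extend(c.nodes())
        return out

    def terminals(self) -> set[str]:
        """Feature names referenced anywhere in the subtree."""
        return {n.feature for n in self.nodes() if n.feature is not None}

    def render(self) -> str:
        if self.is_terminal:
            if self.feature is not None:
                return self.feature
            return format(self.value, "g")
        return f"{self.op}({', '.join(c.render() for c in self.children)})"

    def evaluate(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        """Vectorised raw value of the subtree over row-aligned columns."""
        if self.feature is not None:
            try:
                return np.asarray(columns[self.feature], dtype=float)
            except KeyError:
                raise KeyError(f"terminal feature {self.feature!r} missing from record") from None
        if self.value is not None:
            n = len(next(iter(columns.values()))) if columns else 1
            return np.full(n, float(self.value))
        args = [c.evaluate(columns) for c in self.children]
        op = self.op
        if op == "add":
            return args[0] + args[1]
        if op == "sub":
            return args[0] - args[1]
        if op == "mul":
            return args[0] * args[1]
        if op == "div":  # protected: near-zero denominator yields 1
            denom = args[1]
            safe = np.where(np.abs(denom) < _PROTECTED_EPS, 1.0, denom)
            return np.where(np.abs(denom) < _PROTECTED_EPS, 1.0, args[0] / safe)
        if op == "max":
            return np.maximum(args[0], args[1])
        if op == "min":
            return np.minimum(args[0], args[1])
        if op == "WA":
            r = args[2]
            return r * args[0] + (1.0 - r) * args[1]
        if op == "OWA":
            r = args[2]
            return r * np.maximum(args[0], args[1]) + (1.0 - r) * np.minimum(args[0], args[1])
        if op == "dilator":
            return np.sqrt(np.clip(args[0], 0.0, None))
        if op == "concentrator":
            return args[0] ** 2
        raise ValueError(f"unknown operator {op!r}")


@dataclass
class ExpressionTree:
    """A rooted expression with its dialect tag.

    ``validate`` enforces the dialect's closure rules: fuzzy trees use only
    the fuzzy operator set, their constants are WA/OWA weights in (0, 1),
    and arithmetic trees use only arithmetic operators.
    """

    root: Node
    dialect: str  # "arithmetic" | "fuzzy"

    def __post_init__(self) -> None:
        if self.dialect not in ("arithmetic", "fuzzy"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def validate(self, max_depth: int | None = None) -> None:
        ops = ARITHMETIC_OPS if self.dialect == "arithmetic" else FUZZY_OPS

        def check(node: Node, under_weight: bool) -> None:
            if node.is_terminal:
                if node.value is not None and self.dialect == "fuzzy":
                    if not (0.0 < node.value < 1.0):
                        raise ValueError(
                            f"fuzzy weight constant must lie in (0, 1), got {node.value}"
                        )
                return
            if node.op not in ops:
                raise ValueError(f"operator {node.op!r} not allowed in {self.dialect} dialect")
            if len(node.children) != ops[node.op]:
                raise ValueError(
                    f"operator {node.op} expects {ops[node.op]} arguments, "
                    f"got {len(node.children)}"
                )
            for i, c in enumerate(node.children):
                check(c, under_weight=(node.op in ("WA", "OWA") and i == 2))

        check(self.root, False)
        if max_depth is not None and self.root.depth() > max_depth:
            raise ValueError(f"tree depth {self.root.depth()} exceeds cap {max_depth}")

    def depth(self) -> int:
        return self.root.depth()

    def render(self) -> str:
        return self.root.render()

    def score(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        """Classifier score in [0, 1] per row.

        Arithmetic trees go through the sigmoid; fuzzy trees are returned
        raw (operator closure keeps them in [0, 1]).
        """
        raw = self.root.evaluate(columns)
        if self.dialect == "arithmetic":
            return sigmoid(raw)
        return raw

    def copy(self) -> "ExpressionTree":
        return ExpressionTree(root=self.root.copy(), dialect=self.dialect)


# ---------------------------------------------------------------------------
# Prefix-notation parser
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    cur = ""
    for ch in text:
        if ch in "(),":
            if cur.strip():
                tokens.append(cur.strip())
            cur = ""
            tokens.append(ch)
        else:
            cur += ch
    if cur.strip():
        tokens.append(cur.strip())
    return tokens


def _parse(tokens: list[str], pos: int) -> tuple[Node, int]:
    tok = tokens[pos]
    if pos + 1 < len(tokens) and tokens[pos + 1] == "(":
        children = []
        pos += 2
        while tokens[pos] != ")":
            child, pos = _parse(tokens, pos)
            children.append(child)
            if tokens[pos] == ",":
                pos += 1
        return Node(op=tok, children=children), pos + 1
    try:
        return Node(value=float(tok)), pos + 1
    except ValueError:
        return Node(feature=tok), pos + 1


def parse_expression(text: str, dialect: str) -> ExpressionTree:
    """Parse the plain prefix rendering back into a validated tree.

    Example: ``parse_expression("add(mul(Ax, 0.7), sub(Rt, Rm))", "arithmetic")``.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ValueError("empty expression")
    root, pos = _parse(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in expression: {tokens[pos:]}")
    tree = ExpressionTree(root=root, dialect=dialect)
    tree.validate()
    return tree
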