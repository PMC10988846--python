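"""Boolean logical models of signalling networks.

A Boolean network is an ordered collection of named nodes, each carrying a
binary activity (0/1) and an update rule: a Boolean formula over other nodes.
Each occurrence of a regulator in a rule defines a signed regulatory edge —
positive when the regulator appears under an even number of negations,
negative when odd — so the signed influence graph is derivable from the
rules alone.

Rule files follow the community "targets, factors" dialect: an optional
header line, then one ``target, expression`` line per node.  Expressions use
``!`` (NOT), ``&`` (AND), ``|`` (OR), parentheses and the constants ``0``/``1``,
with precedence NOT > AND > OR.  Node names are case-sensitive identifiers
matching ``[A-Za-z0-9_]+`` (underscores allow fusion nodes such as AR_ERG).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RuleSyntaxError",
    "NetworkValidationError",
    "LogicRule",
    "BooleanNetwork",
    "parse_rules",
    "write_rules",
    "evaluate_rule",
    "influence_graph",
    "influence_digraph",
    "truth_table",
    "semantic_regulators",
    "read_pathway_map",
    "write_pathway_map",
]

NAME_PATTERN = re.compile(r"^[A-Za-z0-9_]+$")
_HEADER_PATTERN = re.compile(r"^\s*targets\s*,\s*factors\s*$", re.IGNORECASE)


class RuleSyntaxError(ValueError):
    """A rule expression (or rule file line) could not be parsed."""


class NetworkValidationError(ValueError):
    """A network violates a structural invariant (duplicate/undeclared node...)."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> FrozenSet[str]:
        raise NotImplementedError

    def signed_literals(self, negated: bool = False) -> FrozenSet[Tuple[str, int]]:
        """Set of (variable, sign) pairs; sign +1 for even negation depth, -1 odd."""
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def evaluate(self, state):
        return self.value

    def variables(self):
        return frozenset()

    def signed_literals(self, negated=False):
        return frozenset()

    def to_text(self):
        return str(self.value)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, state):
        try:
            return 1 if state[self.name] else 0
        except KeyError:
            raise ValueError(f"state is missing a value for node {self.name!r}") from None

    def variables(self):
        return frozenset({self.name})

    def signed_literals(self, negated=False):
        return frozenset({(self.name, -1 if negated else 1)})

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr

    def evaluate(self, state):
        return 1 - self.arg.evaluate(state)

    def variables(self):
        return self.arg.variables()

    def signed_literals(self, negated=False):
        return self.arg.signed_literals(not negated)

    def to_text(self):
        inner = self.arg.to_text()
        if isinstance(self.arg, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(Expr):
    args: Tuple[Expr, ...]

    def evaluate(self, state):
        for a in self.args:
            if not a.evaluate(state):
                return 0
        return 1

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def signed_literals(self, negated=False):
        return frozenset().union(*(a.signed_literals(negated) for a in self.args))

    def to_text(self):
        parts = []
        for a in self.args:
            t = a.to_text()
            if isinstance(a, Or):
                t = f"({t})"
            parts.append(t)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    args: Tuple[Expr, ...]

    def evaluate(self, state):
        for a in self.args:
            if a.evaluate(state):
                return 1
        return 0

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def signed_literals(self, negated=False):
        return frozenset().union(*(a.signed_literals(negated) for a in self.args))

    def to_text(self):
        return " | ".join(a.to_text() for a in self.args)


# ---------------------------------------------------------------------------
# Expression parser (recursive descent; precedence NOT > AND > OR)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z0-9_]+)|(?P<op>[!&|()]))")


def _tokenize(text: str, line_no: Optional[int]) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            remainder = text[pos:].strip()
            if not remainder:
                break
            loc = f" on line {line_no}" if line_no is not None else ""
            raise RuleSyntaxError(
                f"unexpected character {remainder[0]!r} in expression{loc}: {text.strip()!r}"
            )
        if m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, text, line_no=None):
        self.tokens = tokens
        self.i = 0
        self.text = text
        self.line_no = line_no

    def _err(self, msg):
        loc = f" on line {self.line_no}" if self.line_no is not None else ""
        raise RuleSyntaxError(f"{msg}{loc}: {self.text.strip()!r}")

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            self._err("unexpected end of expression")
        self.i += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            self._err("empty expression")
        expr = self._or()
        if self._peek() is not None:
            self._err(f"trailing tokens after expression near {self.tokens[self.i]!r}")
        return expr

    def _or(self) -> Expr:
        args = [self._and()]
        while self._peek() == ("op", "|"):
            self._next()
            args.append(self._and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def _and(self) -> Expr:
        args = [self._unary()]
        while self._peek() == ("op", "&"):
            self._next()
            args.append(self._unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def _unary(self) -> Expr:
        tok = self._peek()
        if tok == ("op", "!"):
            self._next()
            return Not(self._unary())
        return self._atom()

    def _atom(self) -> Expr:
        tok = self._next()
        kind, value = tok
        if kind == "name":
            if value in ("0", "1"):
                return Const(int(value))
            if not NAME_PATTERN.match(value):
                self._err(f"invalid node name {value!r}")
            return Var(value)
        if value == "(":
            expr = self._or()
            if self._next() != ("op", ")"):
                self._err("expected closing parenthesis")
            return expr
        self._err(f"unexpected token {value!r}")


def parse_expression(text: str, line_no: Optional[int] = None) -> Expr:
    """Parse a Boolean expression into an AST."""
    return _Parser(_tokenize(text, line_no), text, line_no).parse()


# ---------------------------------------------------------------------------
# Rules and networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicRule:
    """Update rule for one node: ``target`` takes the value of ``expression``."""

    target: str
    expression: Expr

    def __post_init__(self):
        if not NAME_PATTERN.match(self.target):
            raise NetworkValidationError(f"invalid node name {self.target!r}")

    @property
    def literals(self) -> FrozenSet[Tuple[str, int]]:
        """Signed regulators: (name, +1) under even negations, (name, -1) under odd."""
        return self.expression.signed_literals()

    @property
    def regulators(self) -> Tuple[str, ...]:
        """Variables referenced by the rule, sorted for determinism."""
        return tuple(sorted(self.expression.variables()))

    def to_text(self) -> str:
        return f"{self.target}, {self.expression.to_text()}"


def evaluate_rule(rule: LogicRule, state: Mapping[str, int]) -> int:
    """Value of the rule's expression under a total 0/1 assignment."""
    return rule.expression.evaluate(state)


def truth_table(rule: LogicRule, order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Truth table of a rule over regulators in ``order`` (default: sorted).

    Entry ``i`` is the rule value for the assignment where bit ``j`` of ``i``
    is the value of ``order[j]``.
    """
    if order is None:
        order = rule.regulators
    order = tuple(order)
    missing = set(rule.expression.variables()) - set(order)
    if missing:
        raise ValueError(f"truth-table order is missing regulators {sorted(missing)}")
    k = len(order)
    table = np.empty(2**k, dtype=np.uint8)
    for i in range(2**k):
        state = {name: (i >> j) & 1 for j, name in enumerate(order)}
        table[i] = rule.expression.evaluate(state)
    return table


def semantic_regulators(rule: LogicRule) -> FrozenSet[str]:
    """Regulators the rule truly depends on (flipping them changes the output)."""
    order = rule.regulators
    table = truth_table(rule, order)
    essential = set()
    for j, name in enumerate(order):
        idx = np.arange(table.size)
        if np.any(table[idx] != table[idx ^ (1 << j)]):
            essential.add(name)
    return frozenset(essential)


@dataclass(frozen=True)
class BooleanNetwork:
    """A validated Boolean network: ordered nodes, one rule each.

    ``pathway_groups`` optionally labels nodes with a signalling-pathway name
    (e.g. AR, TGF_beta, Cell_cycle) for pathway-level reporting.
    """

    nodes: Tuple[str, ...]
    rules: Tuple[LogicRule, ...]
    pathway_groups: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "rules", tuple(self.rules))
        seen = set()
        for n in self.nodes:
            if n in seen:
                raise NetworkValidationError(f"duplicate node {n!r}")
            seen.add(n)
        if len(self.rules) != len(self.nodes):
            raise NetworkValidationError(
                f"{len(self.nodes)} nodes but {len(self.rules)} rules; need exactly one rule per node"
            )
        for node, rule in zip(self.nodes, self.rules):
            if rule.target != node:
                raise NetworkValidationError(
                    f"rule order mismatch: node {node!r} paired with rule for {rule.target!r}"
                )
            undeclared = rule.expression.variables() - seen
            if undeclared:
                raise NetworkValidationError(
                    f"rule for {node!r} references undeclared node(s) {sorted(undeclared)}"
                )
        if self.pathway_groups is not None:
            object.__setattr__(self, "pathway_groups", dict(self.pathway_groups))

    def rule(self, node: str) -> LogicRule:
        try:
            return self.rules[self.nodes.index(node)]
        except ValueError:
            raise KeyError(f"no node {node!r} in network") from None

    @property
    def rule_map(self) -> Dict[str, LogicRule]:
        return {n: r for n, r in zip(self.nodes, self.rules)}

    def pathway_of(self, node: str) -> Optional[str]:
        if self.pathway_groups is None:
            return None
        return self.pathway_groups.get(node)

    def __len__(self) -> int:
        return len(self.nodes)


def parse_rules(
    text: str, pathway_groups: Optional[Mapping[str, str]] = None
) -> BooleanNetwork:
    """Parse "targets, factors" rule-file content into a validated network.

    Node order follows file order.  Errors name the offending node, variable
    or line.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty rule file")
    nodes: list = []
    rules: list = []
    seen: Dict[str, int] = {}
    header_allowed = True
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if header_allowed and _HEADER_PATTERN.match(line):
            header_allowed = False
            continue
        header_allowed = False
        if "," not in line:
            raise RuleSyntaxError(
                f"line {line_no}: expected 'target, expression', got {line!r}"
            )
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not NAME_PATTERN.match(target):
            raise RuleSyntaxError(f"line {line_no}: invalid target name {target!r}")
        if target in seen:
            raise NetworkValidationError(
                f"duplicate target {target!r} (lines {seen[target]} and {line_no})"
            )
        seen[target] = line_no
        expression = parse_expression(expr_text, line_no)
        nodes.append(target)
        rules.append(LogicRule(target, expression))
    return BooleanNetwork(tuple(nodes), tuple(rules), pathway_groups)


def write_rules(network: BooleanNetwork) -> str:
    """Serialize a network to rule-file text; re-parsing preserves truth tables."""
    lines = ["targets, factors"]
    for rule in network.rules:
        lines.append(rule.to_text())
    return "\n".join(lines) + "\n"


def influence_graph(network: BooleanNetwork) -> FrozenSet[Tuple[str, str, int]]:
    """Signed directed edges (source, target, sign) of the network.

    Edge (u, v, s) is present iff u occurs in v's rule with sign s; a
    regulator occurring under both parities yields both edges.
    """
    edges = set()
    for rule in network.rules:
        for reg, sign in rule.literals:
            edges.add((reg, rule.target, sign))
    return frozenset(edges)


def influence_digraph(network: BooleanNetwork) -> nx.MultiDiGraph:
    """Influence graph as a networkx MultiDiGraph with a ``sign`` edge attribute."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(network.nodes)
    for u, v, sign in sorted(influence_graph(network)):
        g.add_edge(u, v, sign=sign)
    return g


def downstream_nodes(network: BooleanNetwork, sources: Iterable[str]) -> FrozenSet[str]:
    """Nodes reachable from any source via directed influence edges (sources included)."""
    g = influence_digraph(network)
    reached = set()
    for s in sources:
        if s not in g:
            raise KeyError(f"no node {s!r} in network")
        reached.add(s)
        reached |= nx.descendants(g, s)
    return frozenset(reached)


# ---------------------------------------------------------------------------
# Pathway map I/O: two-column TSV (node, pathway)
# ---------------------------------------------------------------------------


def read_pathway_map(path, network: Optional[BooleanNetwork] = None) -> Dict[str, str]:
    """Read a node→pathway TSV (optional ``node\tpathway`` header).

    Unknown nodes are kept but logged when a network is given.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("pathway map must have two tab-separated columns (node, pathway)")
    if list(df.iloc[0, :2].str.lower()) == ["node", "pathway"]:
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if network is not None:
        unknown = sorted(set(mapping) - set(network.nodes))
        if unknown:
            logger.warning("pathway map contains nodes absent from network: %s", unknown)
    return mapping


def write_pathway_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"node": list(mapping.keys()), "pathway": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
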