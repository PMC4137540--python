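"""Asynchronous Boolean networks: successors, reachability, attractors,
bounded safety checking.

Genes are nodes holding a Boolean value; regulation is encoded as one update
expression per node.  Under asynchronous semantics exactly one node is
updated per transition, so every edge of the state graph flips at most one
bit; a fixed point carries an explicit self-loop.  Attractors are the
terminal strongly connected components of the state graph.

Networks are written either as plain-text rule files (one ``A = !B & C``
line per node; ``!``/``&``/``|`` or ``not``/``and``/``or``) or as JSON.
States are bit-encoded integers (bit i = node i) with a hard cap of 24
nodes for exhaustive exploration.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx

__all__ = [
    "BooleanNetwork",
    "Attractor",
    "parse_rules",
    "async_successors",
    "reachable",
    "find_attractors",
    "check_safety",
    "state_to_int",
    "int_to_state",
    "state_graph",
    "state_graph_to_dot",
]

HARD_CAP = 24  # exhaustive exploration limited to 2^24 states

_BOOL_NODES = (
    ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp, ast.Not,
    ast.Name, ast.Load, ast.Constant,
)


def _compile_update(source: str, nodes: Sequence[str]) -> Callable[[tuple[bool, ...]], bool]:
    normalized = (
        source.replace("&&", " and ").replace("||", " or ")
        .replace("&", " and ").replace("|", " or ").replace("!", " not ")
    ).strip()
    try:
        tree = ast.parse(normalized, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"cannot parse update rule {source!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _BOOL_NODES):
            raise ValueError(
                f"disallowed syntax {type(node).__name__!r} in rule {source!r}"
            )
        if isinstance(node, ast.Constant) and not isinstance(node.value, (bool, int)):
            raise ValueError(f"non-Boolean literal in rule {source!r}")
        if isinstance(node, ast.Name) and node.id not in nodes and node.id not in ("True", "False"):
            raise ValueError(f"unknown node {node.id!r} in rule {source!r}")
    code = compile(tree, f"<rule:{source}>", "eval")
    index = {n: i for i, n in enumerate(nodes)}

    def update(state: tuple[bool, ...]) -> bool:
        ns = {n: state[i] for n, i in index.items()}
        return bool(eval(code, {"__builtins__": {}}, ns))

    return update


class BooleanNetwork:
    """Named nodes with one Boolean update expression per node."""

    def __init__(self, nodes: Sequence[str], update_expressions: dict[str, str]) -> None:
        self.nodes = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node names must be unique")
        missing = set(self.nodes) - set(update_expressions)
        if missing:
            raise ValueError(f"missing update rule for nodes {sorted(missing)}")
        self.update_expressions = {n: update_expressions[n] for n in self.nodes}
        self._updates = [
            _compile_update(update_expressions[n], self.nodes) for n in self.nodes
        ]

    @property
    def n(self) -> int:
        return len(self.nodes)

    def update_node(self, state: tuple[bool, ...], i: int) -> bool:
        return self._updates[i](state)

    @classmethod
    def from_rules(cls, text: str) -> "BooleanNetwork":
        return parse_rules(text)

    @classmethod
    def load(cls, path: str | Path) -> "BooleanNetwork":
        path = Path(path)
        if path.suffix == ".json":
            data = json.loads(path.read_text())
            return cls(data["nodes"], data["update_expressions"])
        return parse_rules(path.read_text())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(
                {"nodes": list(self.nodes),
                 "update_expressions": self.update_expressions}, indent=2))
        else:
            path.write_text("\n".join(
                f"{n} = {e}" for n, e in self.update_expressions.items()) + "\n")


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a plain-text rules file: one ``node = expression`` per line.

    Blank lines and ``#`` comments are ignored; nodes are ordered by first
    appearance on the left-hand side.
    """
    nodes: list[str] = []
    rules: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed rule line: {raw!r}")
        name, expr = line.split("=", 1)
        name = name.strip()
        if name in rules:
            raise ValueError(f"duplicate rule for node {name!r}")
        nodes.append(name)
        rules[name] = expr.strip()
    return BooleanNetwork(nodes, rules)


# ---------------------------------------------------------------------------
# State encoding
# ---------------------------------------------------------------------------


def state_to_int(state: Sequence[bool]) -> int:
    return sum(1 << i for i, v in enumerate(state) if v)


def int_to_state(code: int, n: int) -> tuple[bool, ...]:
    return tuple(bool(code >> i & 1) for i in range(n))


def async_successors(network: BooleanNetwork, state: Sequence[bool]) -> set[tuple[bool, ...]]:
    """All states reachable by updating exactly one node whose value changes.

    A fixed point (no applicable update changes anything) returns the state
    itself — the self-loop convention, so reachability and SCC semantics
    compose cleanly.
    """
    state = tuple(bool(v) for v in state)
    if len(state) != network.n:
        raise ValueError("state length must equal node count")
    succ = set()
    for i in range(network.n):
        new = network.update_node(state, i)
        if new != state[i]:
            succ.add(state[:i] + (new,) + state[i + 1:])
    if not succ:
        succ.add(state)
    return succ


def reachable(
    network: BooleanNetwork,
    init: Iterable[Sequence[bool]],
    target: Callable[[tuple[bool, ...]], bool],
    bound: int | None = None,
) -> tuple[bool, list[tuple[bool, ...]] | None]:
    """Breadth-first search for a target state within *bound* steps.

    ``bound=None`` means unbounded, allowed only for networks up to
    :data:`HARD_CAP` nodes.  On success returns a shortest witness path
    (list of states, init first).
    """
    if bound is None and network.n > HARD_CAP:
        raise ValueError(
            f"unbounded search requires <= {HARD_CAP} nodes; supply a bound"
        )
    if bound is not None and bound < 0:
        raise ValueError("bound must be >= 0")
    frontier = [tuple(bool(v) for v in s) for s in init]
    parent: dict[tuple[bool, ...], tuple[bool, ...] | None] = {
        s: None for s in frontier
    }
    for s in frontier:
        if target(s):
            return True, _path(parent, s)
    depth = 0
    while frontier and (bound is None or depth < bound):
        depth += 1
        nxt = []
        for s in frontier:
            for t in async_successors(network, s):
                if t in parent:
                    continue
                parent[t] = s
                if target(t):
                    return True, _path(parent, t)
                nxt.append(t)
        frontier = nxt
    return False, None


def _path(parent, end):
    path = [end]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


@dataclass(frozen=True)
class Attractor:
    states: frozenset[tuple[bool, ...]]
    kind: str  # "fixed_point" | "cyclic"

    def __len__(self) -> int:
        return len(self.states)


def state_graph(network: BooleanNetwork) -> nx.DiGraph:
    """Full asynchronous state graph over all 2^n states (n <= cap)."""
    if network.n > HARD_CAP:
        raise ValueError(f"state graph limited to {HARD_CAP} nodes")
    g = nx.DiGraph()
    for code in range(1 << network.n):
        s = int_to_state(code, network.n)
        g.add_node(s)
        for t in async_successors(network, s):
            g.add_edge(s, t)
    return g


def find_attractors(network: BooleanNetwork) -> list[Attractor]:
    """Attractors = terminal strongly connected components of the state graph.

    A singleton terminal SCC (necessarily carrying its self-loop) is a fixed
    point; any larger terminal SCC is a cyclic attractor.
    """
    g = state_graph(network)
    cond = nx.condensation(g)
    attractors = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:  # terminal SCC
            states = frozenset(cond.nodes[comp_id]["members"])
            kind = "fixed_point" if len(states) == 1 else "cyclic"
            attractors.append(Attractor(states, kind))
    attractors.sort(key=lambda a: sorted(state_to_int(s) for s in a.states)[0])
    return attractors


def check_safety(
    network: BooleanNetwork,
    init: Iterable[Sequence[bool]],
    invariant: Callable[[tuple[bool, ...]], bool],
    bound: int | None = None,
) -> tuple[bool, list[tuple[bool, ...]] | None]:
    """Bounded safety (AG within bound): no reachable state violates the
    invariant.  Returns (True, None) if safe, else (False, shortest
    counterexample path)."""
    hit, path = reachable(network, init, lambda s: not invariant(s), bound)
    return (not hit), path


def state_graph_to_dot(network: BooleanNetwork) -> str:
    g = state_graph(network)
    lines = ["digraph states {"]
    for s in g.nodes:
        label = "".join("1" if v else "0" for v in s)
        lines.append(f'  "{label}";')
    for s, t in g.edges:
        a = "".join("1" if v else "0" for v in s)
        b = "".join("1" if v else "0" for v in t)
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Illustrative pathway fixture
# ---------------------------------------------------------------------------

#: Original 10-node illustrative pathway network (synthetic, not transcribed
#: from any published model): a ligand-receptor-RAS-like proliferation arm, a
#: P53–MDM2 negative feedback loop producing a cyclic attractor, and an
#: apoptosis readout antagonized by proliferative signaling.
PATHWAY_RULES = """\
ligand = ligand
receptor = ligand
ras = receptor
erk = ras
cyclin = erk & !p21
p53 = !mdm2
mdm2 = p53
p21 = p53 & !erk
proliferation = cyclin
apoptosis = p53 & !cyclin
"""


def make_pathway_network() -> BooleanNetwork:
    """The repository's illustrative signal-transduction Boolean fixture."""
    return parse_rules(PATHWAY_RULES)
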