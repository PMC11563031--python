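"""Admixture graphs and expected f-statistics via weighted path overlaps.

An admixture graph is a rooted DAG of *drift edges* (parent -> child, with a
non-negative length in f-statistic units) plus *admixture nodes* that receive
ancestry from exactly two parents with proportions alpha and 1 - alpha.  The
expected value of any f-statistic is a linear function of the drift-edge
lengths: for each leaf X and drift edge e, let w_{X,e} be the probability
that a lineage sampled from X traverses e; then

    E f4(A,B;C,D) = sum_e (w_{A,e} - w_{B,e}) (w_{C,e} - w_{D,e}) l_e

with f2 and f3 as the definitional special cases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AdmixtureGraph",
    "BranchWeights",
    "DriftEdge",
    "AdmixtureEvent",
    "LinearForm",
    "ParameterCount",
    "GraphValidationError",
    "parse_graph",
    "serialize_graph",
    "branch_weights",
    "expected_f4",
    "expected_f3",
    "expected_f2",
    "admixture_linearity_check",
    "count_parameters",
    "reroot_at_edge",
]


class GraphValidationError(ValueError):
    pass


@dataclass(frozen=True)
class DriftEdge:
    name: str
    parent: str
    child: str
    length: float | None = None


@dataclass(frozen=True)
class AdmixtureEvent:
    child: str
    parents: tuple[str, str]
    alpha: float | None = None  # proportion on parents[0]


class AdmixtureGraph:
    """Validated admixture graph.

    Drift edges carry optional lengths (None = free parameter); admixture
    events carry an optional mixture proportion on the first parent.
    """

    def __init__(self, root: str, edges: list[DriftEdge], admixtures: list[AdmixtureEvent] = ()):
        self.root = root
        self.edges = list(edges)
        self.admixtures = list(admixtures)
        self._validate()

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_edges(
        cls,
        root: str,
        edges: list[tuple],
        admixtures: list[tuple] = (),
    ) -> "AdmixtureGraph":
        """Build from (parent, child[, length]) and (child, p1, p2[, alpha]) tuples."""
        de = []
        for t in edges:
            parent, child = t[0], t[1]
            length = t[2] if len(t) > 2 else None
            de.append(DriftEdge(f"{parent}_{child}", parent, child, length))
        ae = []
        for t in admixtures:
            child, p1, p2 = t[0], t[1], t[2]
            alpha = t[3] if len(t) > 3 else None
            ae.append(AdmixtureEvent(child, (p1, p2), alpha))
        return cls(root, de, ae)

    def _validate(self) -> None:
        g = nx.DiGraph()
        for e in self.edges:
            if g.has_edge(e.parent, e.child):
                raise GraphValidationError(f"duplicate edge {e.parent}->{e.child}")
            g.add_edge(e.parent, e.child, kind="drift", name=e.name, length=e.length)
            if e.length is not None and e.length < -1e-15:
                raise GraphValidationError(f"edge {e.name} has negative length {e.length}")
        names = [e.name for e in self.edges]
        if len(set(names)) != len(names):
            raise GraphValidationError("drift edge names must be unique")
        seen_admix = set()
        for a in self.admixtures:
            if a.child in seen_admix:
                raise GraphValidationError(f"node {a.child} has more than one admixture event")
            seen_admix.add(a.child)
            if len(set(a.parents)) != 2:
                raise GraphValidationError(
                    f"admixture node {a.child} needs two distinct parents, got {a.parents}"
                )
            if a.alpha is not None and not (0.0 <= a.alpha <= 1.0):
                raise GraphValidationError(
                    f"admixture proportion for {a.child} must be in [0, 1], got {a.alpha}"
                )
            for p in a.parents:
                g.add_edge(p, a.child, kind="mix")
        if self.root not in g:
            raise GraphValidationError(f"declared root {self.root!r} has no edges")
        if not nx.is_directed_acyclic_graph(g):
            raise GraphValidationError("graph contains a cycle")
        roots = [n for n in g if g.in_degree(n) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise GraphValidationError(
                f"expected single root {self.root!r}, found parentless nodes {sorted(roots)}"
            )
        for n in g:
            kinds = [g.edges[p, n]["kind"] for p in g.predecessors(n)]
            if n == self.root:
                if kinds:
                    raise GraphValidationError("root cannot have parents")
            elif kinds == ["drift"]:
                pass
            elif sorted(kinds) == ["mix", "mix"]:
                pass
            else:
                raise GraphValidationError(
                    f"node {n!r} must have one drift parent or two admixture parents, "
                    f"found {kinds or 'none'}"
                )
        self._g = g
        self._topo = list(nx.topological_sort(g))

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._topo)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_admixture(self) -> int:
        return len(self.admixtures)

    @property
    def edge_names(self) -> list[str]:
        return [e.name for e in self.edges]

    @property
    def lengths(self) -> dict[str, float | None]:
        return {e.name: e.length for e in self.edges}

    @property
    def alphas(self) -> dict[str, float | None]:
        return {a.child: a.alpha for a in self.admixtures}

    def edge(self, name: str) -> DriftEdge:
        for e in self.edges:
            if e.name == name:
                return e
        raise GraphValidationError(f"no drift edge named {name!r}")

    def children(self, node: str) -> list[str]:
        return list(self._g.successors(node))

    def parents(self, node: str) -> list[str]:
        return list(self._g.predecessors(node))

    def subtree_leaves(self, node: str) -> set[str]:
        return {n for n in nx.descendants(self._g, node) | {node} if self._g.out_degree(n) == 0}

    def with_params(
        self,
        lengths: dict[str, float] | None = None,
        alphas: dict[str, float] | None = None,
    ) -> "AdmixtureGraph":
        """Copy of the graph with some lengths / proportions replaced."""
        lengths = lengths or {}
        alphas = alphas or {}
        edges = [
            DriftEdge(e.name, e.parent, e.child, lengths.get(e.name, e.length))
            for e in self.edges
        ]
        admix = [
            AdmixtureEvent(a.child, a.parents, alphas.get(a.child, a.alpha))
            for a in self.admixtures
        ]
        return AdmixtureGraph(self.root, edges, admix)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AdmixtureGraph)
            and self.root == other.root
            and set(self.edges) == set(other.edges)
            and set(self.admixtures) == set(other.admixtures)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AdmixtureGraph(root={self.root!r}, {len(self.edges)} drift edges, "
            f"{self.n_admixture} admixture events, leaves={self.leaves})"
        )


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def parse_graph(text: str) -> AdmixtureGraph:
    """Parse the qpGraph-style text dialect.

    Grammar (one directive per line, '#' comments)::

        root  R
        edge  <name> <parent> <child> [length]
        admix <child> <parent1> <parent2> [alpha]
    """
    root = None
    edges: list[DriftEdge] = []
    admix: list[AdmixtureEvent] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = _WS.split(line)
        try:
            if tok[0] == "root" and len(tok) == 2:
                if root is not None:
                    raise GraphValidationError("multiple root directives")
                root = tok[1]
            elif tok[0] == "edge" and len(tok) in (4, 5):
                length = float(tok[4]) if len(tok) == 5 else None
                edges.append(DriftEdge(tok[1], tok[2], tok[3], length))
            elif tok[0] == "admix" and len(tok) in (4, 5):
                alpha = float(tok[4]) if len(tok) == 5 else None
                admix.append(AdmixtureEvent(tok[1], (tok[2], tok[3]), alpha))
            else:
                raise GraphValidationError(f"unrecognized directive {tok[0]!r}")
        except (ValueError, GraphValidationError) as exc:
            raise GraphValidationError(f"line {lineno}: {exc}") from None
    if root is None:
        raise GraphValidationError("missing 'root' directive")
    return AdmixtureGraph(root, edges, admix)


def serialize_graph(graph: AdmixtureGraph, format: str = "text") -> str:
    """Serialize to the text dialect or to Graphviz DOT.

    DOT edge labels follow the field's display convention: drift lengths are
    multiplied by 1000 and rounded to the nearest integer, mixture
    proportions shown as whole percentages.
    """
    if format == "text":
        lines = [f"root {graph.root}"]
        for e in graph.edges:
            tail = "" if e.length is None else f" {e.length:.10g}"
            lines.append(f"edge {e.name} {e.parent} {e.child}{tail}")
        for a in graph.admixtures:
            tail = "" if a.alpha is None else f" {a.alpha:.10g}"
            lines.append(f"admix {a.child} {a.parents[0]} {a.parents[1]}{tail}")
        return "\n".join(lines) + "\n"
    if format == "dot":
        lines = ["digraph G {", "  node [shape=ellipse];"]
        for leaf in graph.leaves:
            lines.append(f'  "{leaf}" [shape=box];')
        for e in graph.edges:
            label = "?" if e.length is None else str(int(round(1000 * e.length)))
            lines.append(f'  "{e.parent}" -> "{e.child}" [label="{label}"];')
        for a in graph.admixtures:
            for p, frac in zip(a.parents, (a.alpha, None if a.alpha is None else 1 - a.alpha)):
                label = "?" if frac is None else f"{round(100 * frac)}%"
                lines.append(f'  "{p}" -> "{a.child}" [style=dashed, label="{label}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# branch weights and expected f-statistics
# ---------------------------------------------------------------------------


@dataclass
class BranchWeights:
    """w[leaf][edge] = probability a lineage from the leaf traverses the edge."""

    leaves: list[str]
    edge_names: list[str]
    matrix: np.ndarray  # (n_leaves, n_edges)
    _leaf_idx: dict = field(default_factory=dict)
    _edge_idx: dict = field(default_factory=dict)

    def __post_init__(self):
        self._leaf_idx = {l: i for i, l in enumerate(self.leaves)}
        self._edge_idx = {e: i for i, e in enumerate(self.edge_names)}

    def weight(self, leaf: str, edge: str) -> float:
        return float(self.matrix[self._leaf_idx[leaf], self._edge_idx[edge]])

    def row(self, leaf: str) -> np.ndarray:
        return self.matrix[self._leaf_idx[leaf]]


def _node_reach(graph: AdmixtureGraph, leaf: str, alphas: dict[str, float]) -> dict[str, float]:
    """Probability the leaf's lineage passes through each node (root-ward DP)."""
    reach = {n: 0.0 for n in graph.nodes}
    reach[leaf] = 1.0
    for node in reversed(graph.nodes):  # leaf-to-root order
        r = reach[node]
        if r == 0.0 or node == graph.root:
            continue
        parents = graph.parents(node)
        if len(parents) == 1:
            reach[parents[0]] += r
        else:
            a = alphas[node]
            event = next(x for x in graph.admixtures if x.child == node)
            reach[event.parents[0]] += a * r
            reach[event.parents[1]] += (1.0 - a) * r
    return reach


def _resolve_alphas(graph: AdmixtureGraph, alphas: dict[str, float] | None) -> dict[str, float]:
    out = {}
    for a in graph.admixtures:
        val = (alphas or {}).get(a.child, a.alpha)
        if val is None:
            raise GraphValidationError(
                f"admixture proportion for {a.child} is unset; fix it or pass alphas="
            )
        out[a.child] = float(val)
    return out


def branch_weights(graph: AdmixtureGraph, alphas: dict[str, float] | None = None) -> BranchWeights:
    """Exact per-leaf traversal probabilities for every drift edge."""
    alphas = _resolve_alphas(graph, alphas)
    leaves = graph.leaves
    edge_names = graph.edge_names
    edge_idx = {e: i for i, e in enumerate(edge_names)}
    W = np.zeros((len(leaves), len(edge_names)))
    for i, leaf in enumerate(leaves):
        reach = _node_reach(graph, leaf, alphas)
        for e in graph.edges:
            W[i, edge_idx[e.name]] = reach[e.child]
    return BranchWeights(leaves, edge_names, W)


@dataclass
class LinearForm:
    """An expected f-statistic as a linear form over drift-edge lengths."""

    kind: str
    pops: tuple[str, ...]
    coefficients: dict[str, float]
    value: float | None  # None when some involved edge length is free

    def evaluate(self, lengths: dict[str, float]) -> float:
        return float(sum(c * lengths[e] for e, c in self.coefficients.items()))


def _linear_form(graph, kind, pops, rows, weights) -> LinearForm:
    if kind == "f4":
        a, b, c, d = rows
        coef = (weights.row(a) - weights.row(b)) * (weights.row(c) - weights.row(d))
    elif kind == "f3":
        a, b, c = rows
        coef = (weights.row(a) - weights.row(b)) * (weights.row(a) - weights.row(c))
    else:  # f2
        a, b = rows
        coef = (weights.row(a) - weights.row(b)) ** 2
    coefficients = dict(zip(weights.edge_names, coef.tolist()))
    lengths = graph.lengths
    if any(lengths[e] is None for e, c in coefficients.items() if c != 0.0):
        value = None
    else:
        value = float(sum(c * lengths[e] for e, c in coefficients.items() if c != 0.0))
    return LinearForm(kind, tuple(pops), coefficients, value)


def _check_leaves(graph: AdmixtureGraph, pops) -> None:
    leaves = set(graph.leaves)
    for p in pops:
        if p not in leaves:
            raise GraphValidationError(f"{p!r} is not a leaf of the graph (leaves: {sorted(leaves)})")


def expected_f4(graph: AdmixtureGraph, A: str, B: str, C: str, D: str,
                weights: BranchWeights | None = None) -> LinearForm:
    """E f4(A,B;C,D) as coefficients c_e = (wA - wB)(wC - wD) per drift edge."""
    _check_leaves(graph, (A, B, C, D))
    weights = weights or branch_weights(graph)
    return _linear_form(graph, "f4", (A, B, C, D), (A, B, C, D), weights)


def expected_f3(graph: AdmixtureGraph, A: str, B: str, C: str,
                weights: BranchWeights | None = None) -> LinearForm:
    _check_leaves(graph, (A, B, C))
    weights = weights or branch_weights(graph)
    return _linear_form(graph, "f3", (A, B, C), (A, B, C), weights)


def expected_f2(graph: AdmixtureGraph, A: str, B: str,
                weights: BranchWeights | None = None) -> LinearForm:
    _check_leaves(graph, (A, B))
    weights = weights or branch_weights(graph)
    return _linear_form(graph, "f2", (A, B), (A, B), weights)


# ---------------------------------------------------------------------------
# admixture linearity identity
# ---------------------------------------------------------------------------


@dataclass
class LinearityReport:
    lhs: float
    rhs: float
    alpha: float
    source_terms: tuple[float, float]

    @property
    def holds(self) -> bool:
        return abs(self.lhs - self.rhs) < 1e-12 * max(1.0, abs(self.lhs))


def _admixture_above(graph: AdmixtureGraph, leaf: str) -> AdmixtureEvent:
    """Nearest admixture event on the pure-drift chain above a leaf."""
    node = leaf
    admix_children = {a.child: a for a in graph.admixtures}
    while True:
        if node in admix_children:
            return admix_children[node]
        parents = graph.parents(node)
        if len(parents) != 1 or len(graph.children(parents[0])) != 1:
            raise GraphValidationError(f"{leaf!r} is not an admixed leaf")
        node = parents[0]


def admixture_linearity_check(
    graph: AdmixtureGraph, A: str, B: str, C: str, D: str
) -> LinearityReport:
    """Verify f4(A,B;C,D) = a f4(A,B;C',D) + (1-a) f4(A,B;C'',D) exactly.

    C must be an admixed leaf; C' and C'' are zero-length ghost leaves
    grafted at its two source positions.
    """
    _check_leaves(graph, (A, B, C, D))
    event = _admixture_above(graph, C)
    if event.alpha is None:
        raise GraphValidationError(f"admixture proportion for {event.child} is unset")
    ghosts = []
    edges = list(graph.edges)
    for k, parent in enumerate(event.parents):
        ghost = f"__ghost{k}__"
        edges.append(DriftEdge(f"__ghost_edge{k}__", parent, ghost, 0.0))
        ghosts.append(ghost)
    grafted = AdmixtureGraph(graph.root, edges, graph.admixtures)
    lhs = expected_f4(grafted, A, B, C, D).value
    t1 = expected_f4(grafted, A, B, ghosts[0], D).value
    t2 = expected_f4(grafted, A, B, ghosts[1], D).value
    if lhs is None or t1 is None or t2 is None:
        raise GraphValidationError("all involved branch lengths must be set")
    a = event.alpha
    return LinearityReport(lhs=lhs, rhs=a * t1 + (1 - a) * t2, alpha=a, source_terms=(t1, t2))


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------


@dataclass
class ParameterCount:
    n_constraints: int       # n(n-1)/2 linearly independent f-statistics
    n_free_parameters: int   # 2n + 2a - 3
    compound_reductions: list[str]  # admixture nodes whose surrounding triple is compound


def count_parameters(graph: AdmixtureGraph) -> ParameterCount:
    """Constraint and free-parameter counts for a graph with n leaves, a events.

    An admixture event whose admixed side leads to a single leaf and whose
    two sources are unsampled (stub nodes with no other descendants) is
    listed as a compound reduction: the three surrounding branch lengths
    x, y, z only enter expectations through a^2 x + (1-a)^2 y + z.
    """
    n = graph.n_leaves
    a = graph.n_admixture
    compound = []
    for event in graph.admixtures:
        if len(graph.subtree_leaves(event.child)) != 1:
            continue
        unsampled = all(
            set(graph.children(p)) == {event.child} for p in event.parents
        )
        if unsampled:
            compound.append(event.child)
    return ParameterCount(
        n_constraints=n * (n - 1) // 2,
        n_free_parameters=2 * n + 2 * a - 3,
        compound_reductions=compound,
    )


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------


def reroot_at_edge(graph: AdmixtureGraph, edge_name: str, fraction: float = 0.5) -> AdmixtureGraph:
    """Re-root the graph at a point along a drift edge.

    The chosen edge (p -> c, length l) is split at ``fraction`` from the
    child end into NEWROOT -> c (fraction * l) and NEWROOT -> p
    ((1 - fraction) * l); all drift edges on the path from p up to the old
    root are reversed.  Expected f-statistics are invariant under this
    operation.  Rerooting through an admixture node is not defined.
    """
    target = graph.edge(edge_name)
    if target.length is None:
        raise GraphValidationError("cannot reroot along an edge with free length")
    # path from target.parent up to the root via drift edges
    path = []
    node = target.parent
    while node != graph.root:
        parents = graph.parents(node)
        if len(parents) != 1:
            raise GraphValidationError(
                f"cannot reroot: path to old root passes through admixture node {node!r}"
            )
        edge = next(e for e in graph.edges if e.child == node and e.parent == parents[0])
        path.append(edge)
        node = parents[0]
    new_root = "__root__"
    edges = []
    reversed_names = {e.name for e in path} | {target.name}
    for e in graph.edges:
        if e.name not in reversed_names:
            edges.append(e)
    edges.append(DriftEdge(target.name + ".c", new_root, target.child, fraction * target.length))
    edges.append(DriftEdge(target.name + ".p", new_root, target.parent, (1 - fraction) * target.length))
    for e in path:
        edges.append(DriftEdge(e.name, e.child, e.parent, e.length))
    return AdmixtureGraph(new_root, edges, graph.admixtures)
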