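"""Mixed (partially directed) graphs and DAG -> CPDAG conversion.

A :class:`MixedGraph` holds at most one edge per unordered node pair, each
marked either undirected or directed.  It serves as skeleton, PDAG and CPDAG
container.  ``cpdag_of_dag`` maps a DAG to the canonical representative of its
Markov equivalence class: keep the skeleton, keep v-structure arrowheads, and
close under the Meek propagation rules R1-R3.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

__all__ = ["MixedGraph", "cpdag_of_dag", "read_edge_list", "write_edge_list"]

UNDIRECTED = "--"
DIRECTED = "->"


class MixedGraph:
    """Nodes plus edges marked undirected or directed (one edge per pair)."""

    def __init__(self, nodes=()):
        self._nodes: dict[str, None] = {}
        # key: (a, b) with a < b; value: UNDIRECTED, or (tail, head) for directed
        self._edges: dict[tuple[str, str], object] = {}
        for n in nodes:
            self.add_node(n)

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._nodes.setdefault(str(node), None)

    def add_edge(self, a: str, b: str, directed: bool = False) -> None:
        """Add a-b (undirected) or a->b (directed); replaces any existing mark."""
        a, b = str(a), str(b)
        if a == b:
            raise ValueError("self-loops are not allowed")
        self.add_node(a)
        self.add_node(b)
        self._edges[self._key(a, b)] = (a, b) if directed else UNDIRECTED

    def remove_edge(self, a: str, b: str) -> None:
        del self._edges[self._key(a, b)]

    def orient(self, tail: str, head: str) -> None:
        """Direct an existing edge as tail -> head."""
        key = self._key(tail, head)
        if key not in self._edges:
            raise KeyError(f"no edge between {tail} and {head}")
        self._edges[key] = (tail, head)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    def has_node(self, node: str) -> bool:
        return node in self._nodes

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._edges

    def is_directed_edge(self, tail: str, head: str) -> bool:
        """True iff the edge exists and is directed exactly tail -> head."""
        return self._edges.get(self._key(tail, head)) == (tail, head)

    def is_undirected_edge(self, a: str, b: str) -> bool:
        return self._edges.get(self._key(a, b)) == UNDIRECTED

    def edges(self):
        """Yield (a, b, mark): mark '--' with a<b, or '->' meaning a->b."""
        for key, mark in self._edges.items():
            if mark == UNDIRECTED:
                yield key[0], key[1], UNDIRECTED
            else:
                yield mark[0], mark[1], DIRECTED

    def n_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, node: str) -> set[str]:
        """Adjacent nodes regardless of edge mark."""
        out = set()
        for a, b in self._edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def parents(self, node: str) -> set[str]:
        return {
            mark[0]
            for mark in self._edges.values()
            if mark != UNDIRECTED and mark[1] == node
        }

    def skeleton_pairs(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def copy(self) -> "MixedGraph":
        g = MixedGraph(self._nodes)
        g._edges = dict(self._edges)
        return g

    def skeleton(self) -> "MixedGraph":
        g = MixedGraph(self._nodes)
        for a, b in self._edges:
            g.add_edge(a, b)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __repr__(self) -> str:
        return f"MixedGraph({len(self._nodes)} nodes, {len(self._edges)} edges)"

    def is_dag(self) -> bool:
        """All edges directed and acyclic."""
        if any(mark == UNDIRECTED for mark in self._edges.values()):
            return False
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(m for m in self._edges.values())
        return nx.is_directed_acyclic_graph(g)

    def to_networkx(self) -> nx.DiGraph:
        """DiGraph view: undirected edges become reciprocal arc pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for a, b, mark in self.edges():
            g.add_edge(a, b)
            if mark == UNDIRECTED:
                g.add_edge(b, a)
        return g


def _meek_closure(g: MixedGraph) -> None:
    """Apply Meek rules R1-R3 in place until fixpoint."""
    changed = True
    while changed:
        changed = False
        for a, b in list(g.skeleton_pairs()):
            for tail, head in ((a, b), (b, a)):
                if not g.is_undirected_edge(tail, head):
                    continue
                # R1: c -> tail, c and head non-adjacent  =>  tail -> head
                if any(
                    not g.has_edge(c, head)
                    for c in g.parents(tail)
                    if c != head
                ):
                    g.orient(tail, head)
                    changed = True
                    continue
                # R2: tail -> c -> head with tail - head  =>  tail -> head
                if any(
                    g.is_directed_edge(tail, c) and g.is_directed_edge(c, head)
                    for c in g.neighbors(tail) & g.neighbors(head)
                ):
                    g.orient(tail, head)
                    changed = True
                    continue
                # R3: tail - c, tail - d, c -> head, d -> head, c,d non-adjacent
                cands = [
                    c
                    for c in g.neighbors(tail) & g.parents(head)
                    if g.is_undirected_edge(tail, c)
                ]
                if any(
                    not g.has_edge(c, d)
                    for c, d in combinations(sorted(cands), 2)
                ):
                    g.orient(tail, head)
                    changed = True


def cpdag_of_dag(dag: MixedGraph) -> MixedGraph:
    """Canonical CPDAG of a DAG's Markov equivalence class.

    Keeps the skeleton, orients the v-structures (colliders with non-adjacent
    parents), then closes under Meek R1-R3.  Raises on cyclic or partially
    undirected input.
    """
    if not dag.is_dag():
        raise ValueError("input must be a fully directed acyclic graph")
    out = dag.skeleton()
    for z in dag.nodes:
        for x, y in combinations(sorted(dag.parents(z)), 2):
            if not dag.has_edge(x, y):
                out.orient(x, z)
                out.orient(y, z)
    _meek_closure(out)
    return out


def write_edge_list(graph: MixedGraph, path) -> None:
    """TSV edge list: node_a <TAB> mark <TAB> node_b, mark in {--, ->}."""
    with open(path, "w") as fh:
        for a, b, mark in sorted(graph.edges()):
            fh.write(f"{a}\t{mark}\t{b}\n")


def read_edge_list(path, nodes=()) -> MixedGraph:
    g = MixedGraph(nodes)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[1] not in (UNDIRECTED, DIRECTED):
                raise ValueError(f"bad edge-list line: {line!r}")
            a, mark, b = parts
            g.add_edge(a, b, directed=(mark == DIRECTED))
    return g
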