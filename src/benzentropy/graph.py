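"""Undirected simple graphs and the two structural operators the entropy
pipeline composes: subdivision ``S(G)`` and line graph ``L(G)``.

A :class:`MolecularGraph` is immutable; operators return new graphs, so
``line_graph(subdivision(g))`` composes without aliasing surprises.  Vertex
identifiers are opaque but totally ordered through :func:`vertex_sort_key`,
which makes every derived object (edge lists, partitions, serialized output)
reproducible across runs.

Naming conventions for derived vertices:

* ``subdivision`` inserts one degree-2 vertex per edge, named
  ``('s', u, v)`` where ``(u, v)`` is the subdivided edge in canonical
  (low, high) order.
* ``line_graph`` uses the canonical source-edge pair ``(u, v)`` itself as
  the new vertex identifier, so the bijection between line-graph vertices
  and source edges is the identity and never needs a side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .errors import ParameterError, UnknownVertexError

VertexId = Hashable
Edge = tuple


def vertex_sort_key(v):
    """Total order over heterogeneous vertex identifiers.

    Integers sort numerically, strings lexicographically, tuples
    recursively element-wise; mixed types sort by a fixed type rank.  The
    order is arbitrary but deterministic, which is all canonicalization
    needs.
    """
    if isinstance(v, bool):  # bool is an int subclass; keep it distinct
        return (3, v)
    if isinstance(v, int):
        return (0, v)
    if isinstance(v, str):
        return (1, v)
    if isinstance(v, tuple):
        return (2, tuple(vertex_sort_key(x) for x in v))
    return (4, type(v).__name__, repr(v))


def canonical_edge(u, v) -> Edge:
    """Unordered pair in canonical (low, high) order; rejects self-loops."""
    if u == v:
        raise ParameterError(f"self-loop at vertex {u!r} is not allowed")
    if vertex_sort_key(u) <= vertex_sort_key(v):
        return (u, v)
    return (v, u)


def vertex_token(v) -> str:
    """Deterministic whitespace-free string form of a vertex identifier,
    used by the edge-list and GraphML writers."""
    if isinstance(v, tuple):
        return "(" + ",".join(vertex_token(x) for x in v) + ")"
    s = str(v)
    if not s or any(c.isspace() for c in s) or s.startswith("#"):
        raise ParameterError(f"vertex id {v!r} cannot be serialized as a token")
    return s


@dataclass(frozen=True)
class MolecularGraph:
    """Immutable undirected simple graph.

    ``vertices`` and ``edges`` are stored as sorted tuples (edges in
    canonical low-high order), so two graphs with the same vertex and edge
    sets compare equal and serialize identically.
    """

    vertices: tuple = field(default=())
    edges: tuple = field(default=())

    @classmethod
    def from_edges(cls, edges: Iterable, isolated: Iterable = ()) -> "MolecularGraph":
        """Build a graph from an edge iterable, deduplicating parallel
        edges, plus optional isolated vertices."""
        es = {canonical_edge(u, v) for u, v in edges}
        vs = {v for e in es for v in e} | set(isolated)
        return cls(
            vertices=tuple(sorted(vs, key=vertex_sort_key)),
            edges=tuple(sorted(es, key=lambda e: (vertex_sort_key(e[0]), vertex_sort_key(e[1])))),
        )

    def __post_init__(self):
        vs = set(self.vertices)
        for u, v in self.edges:
            if u == v:
                raise ParameterError(f"self-loop at {u!r}")
            if u not in vs or v not in vs:
                raise ParameterError(f"edge ({u!r}, {v!r}) has an undeclared endpoint")
        if len(set(self.edges)) != len(self.edges):
            raise ParameterError("parallel edges are not allowed")
        if len(vs) != len(self.vertices):
            raise ParameterError("duplicate vertex identifiers")

    # -- basic accessors ---------------------------------------------------

    @cached_property
    def _adjacency(self) -> Mapping:
        adj = {v: [] for v in self.vertices}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v) -> tuple:
        try:
            return tuple(self._adjacency[v])
        except KeyError:
            raise UnknownVertexError(f"unknown vertex {v!r}") from None

    def degree(self, v) -> int:
        """Number of neighbors of ``v``."""
        return len(self.neighbors(v))

    def neighbor_degree_sum(self, v) -> int:
        """Sum of the degrees of the neighbors of ``v`` (the quantity the
        degree-sum edge partitions and the ABC4/GA5 schemes are built on)."""
        return sum(self.degree(u) for u in self.neighbors(v))

    def degree_counts(self) -> dict:
        """Histogram mapping degree -> number of vertices of that degree."""
        out: dict = {}
        for v in self.vertices:
            d = self.degree(v)
            out[d] = out.get(d, 0) + 1
        return out

    def is_connected(self) -> bool:
        if self.n_vertices == 0:
            return True
        seen = {self.vertices[0]}
        stack = [self.vertices[0]]
        while stack:
            for u in self._adjacency[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == self.n_vertices

    # -- structural operators ----------------------------------------------

    def subdivision(self) -> "MolecularGraph":
        """Replace every edge by a path of length two.

        The inserted vertex for edge ``(u, v)`` is ``('s', u, v)``.  The
        result has ``|V| + |E|`` vertices and ``2|E|`` edges; original
        vertices keep their degrees and every inserted vertex has degree 2.
        """
        new_edges = []
        for u, v in self.edges:
            w = ("s", u, v)
            new_edges.append((u, w))
            new_edges.append((w, v))
        return MolecularGraph.from_edges(new_edges, isolated=self.vertices)

    def line_graph(self) -> "MolecularGraph":
        """Line graph: one vertex per edge of ``self``, adjacent iff the
        source edges share an endpoint.

        Line-graph vertex identifiers are the canonical source-edge pairs,
        so the edge ↔ vertex bijection is exposed by construction.  The
        output has ``sum(C(deg(v), 2))`` edges.
        """
        incident = {v: [] for v in self.vertices}
        for e in self.edges:
            incident[e[0]].append(e)
            incident[e[1]].append(e)
        new_edges = []
        for v in self.vertices:
            for e, f in combinations(incident[v], 2):
                new_edges.append((e, f))
        return MolecularGraph.from_edges(new_edges, isolated=self.edges)

    # -- interchange --------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MolecularGraph":
        return cls.from_edges(g.edges(), isolated=g.nodes())


# -- file formats -----------------------------------------------------------


def write_edgelist(g: MolecularGraph, path) -> None:
    """One edge per line, two whitespace-separated vertex tokens.
    Isolated vertices are recorded on single-token lines."""
    with open(path, "w") as fh:
        fh.write("# benzentropy edge list\n")
        connected = {v for e in g.edges for v in e}
        for v in g.vertices:
            if v not in connected:
                fh.write(f"{vertex_token(v)}\n")
        for u, v in g.edges:
            fh.write(f"{vertex_token(u)}\t{vertex_token(v)}\n")


def read_edgelist(path) -> MolecularGraph:
    """Read the TSV edge-list format ('#' comments ignored).  Vertex
    identifiers come back as plain string tokens."""
    edges = []
    isolated = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                isolated.append(parts[0])
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise ParameterError(f"malformed edge-list line: {line!r}")
    return MolecularGraph.from_edges(edges, isolated=isolated)


def write_graphml(g: MolecularGraph, path) -> None:
    """GraphML writer (vertex ids serialized with :func:`vertex_token`)."""
    h = nx.relabel_nodes(g.to_networkx(), {v: vertex_token(v) for v in g.vertices})
    nx.write_graphml(h, path)


def read_graphml(path) -> MolecularGraph:
    return MolecularGraph.from_networkx(nx.read_graphml(path))
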