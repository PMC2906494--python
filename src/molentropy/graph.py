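"""Labeled molecular graph model.

A :class:`LabeledGraph` is a finite, connected, loop-free undirected graph
in which every vertex carries a symbol from a vertex alphabet (atom types
such as ``"C"``, ``"N"``, ``"O"``) and every edge carries a symbol from an
edge alphabet (bond types ``"s"``, ``"d"``, ``"t"``, ``"ar"`` for single,
double, triple and aromatic bonds).  Vertices are identified by 0-based
integer ids.  The topology is stored in a :class:`networkx.Graph` with the
labels as node/edge attributes, so the full networkx toolbox remains
available via :attr:`LabeledGraph.nx`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

#: sentinel used for skeletons, where atom and bond identity is erased
SKELETON_VERTEX = "*"
SKELETON_EDGE = "-"


class GraphError(ValueError):
    """Raised when a structure violates the labeled-graph model."""


class LabeledGraph:
    """Connected, loop-free undirected graph with vertex and edge labels.

    Parameters
    ----------
    graph:
        networkx graph whose nodes are ``0..n-1`` and whose nodes/edges all
        carry a ``"label"`` attribute.
    name:
        free-text structure identifier.
    """

    __slots__ = ("nx", "name")

    def __init__(self, graph: nx.Graph, name: str = ""):
        _validate(graph)
        self.nx = graph
        self.name = name

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_labels(
        cls,
        vertex_labels: Iterable[str] | Mapping[int, str],
        edges: Iterable[tuple[int, int, str]],
        name: str = "",
    ) -> "LabeledGraph":
        """Build a graph from vertex labels and ``(u, v, bond_label)`` triples."""
        if isinstance(vertex_labels, Mapping):
            items = sorted(vertex_labels.items())
        else:
            items = list(enumerate(vertex_labels))
        g = nx.Graph()
        for v, lab in items:
            g.add_node(v, label=str(lab))
        for u, v, lab in edges:
            g.add_edge(u, v, label=str(lab))
        return cls(g, name=name)

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.nx.number_of_nodes()

    @property
    def m(self) -> int:
        return self.nx.number_of_edges()

    @property
    def vertices(self) -> list[int]:
        return sorted(self.nx.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(min(u, v), max(u, v)) for u, v in self.nx.edges]

    def vertex_label(self, v: int) -> str:
        return self.nx.nodes[v]["label"]

    def edge_label(self, u: int, v: int) -> str:
        return self.nx.edges[u, v]["label"]

    @property
    def vertex_labels(self) -> dict[int, str]:
        return {v: d["label"] for v, d in self.nx.nodes(data=True)}

    @property
    def edge_labels(self) -> dict[tuple[int, int], str]:
        return {
            (min(u, v), max(u, v)): d["label"] for u, v, d in self.nx.edges(data=True)
        }

    @property
    def vertex_alphabet(self) -> tuple[str, ...]:
        """Distinct vertex labels present, sorted."""
        return tuple(sorted({d["label"] for _, d in self.nx.nodes(data=True)}))

    @property
    def edge_alphabet(self) -> tuple[str, ...]:
        return tuple(sorted({d["label"] for _, _, d in self.nx.edges(data=True)}))

    # -- misc --------------------------------------------------------------

    def relabel(self, mapping: Mapping[int, int], name: str | None = None) -> "LabeledGraph":
        """Return an isomorphic copy with vertex ids permuted by *mapping*."""
        g = nx.relabel_nodes(self.nx, dict(mapping), copy=True)
        return LabeledGraph(g, name=self.name if name is None else name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.name!r}" if self.name else ""
        return f"<LabeledGraph{tag} |V|={self.n} |E|={self.m}>"


def to_skeleton(g: LabeledGraph) -> LabeledGraph:
    """Erase all atom and bond identity, keeping topology only.

    All vertex labels become the sentinel ``"*"`` and all edge labels the
    sentinel ``"-"``; applying the operation twice is a no-op.
    """
    s = g.nx.copy()
    nx.set_node_attributes(s, SKELETON_VERTEX, "label")
    nx.set_edge_attributes(s, SKELETON_EDGE, "label")
    return LabeledGraph(s, name=g.name)


def _validate(graph: nx.Graph) -> None:
    if graph.number_of_nodes() < 1:
        raise GraphError("graph must have at least one vertex")
    if any(u == v for u, v in graph.edges):
        raise GraphError("self-loops are not allowed")
    if not nx.is_connected(graph):
        raise GraphError("graph must be connected")
    for v, d in graph.nodes(data=True):
        if "label" not in d:
            raise GraphError(f"vertex {v} has no label")
    for u, v, d in graph.edges(data=True):
        if "label" not in d:
            raise GraphError(f"edge ({u}, {v}) has no label")
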