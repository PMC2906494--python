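"""Distance structure of a graph.

Shortest-path distances, eccentricities, diameter, j-spheres (with and
without vertex-label restriction) and local information graphs — the union
of all shortest paths of a given length starting at a vertex.  Everything
here works on unweighted hop distances; edge labels only become numeric
weights later, inside the edge information functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

from .graph import LabeledGraph


@dataclass(frozen=True)
class DistanceIndex:
    """All-pairs shortest-path summary of a connected graph.

    Attributes
    ----------
    dist:
        ``dist[u][v]`` shortest-path length in hops.
    ecc:
        eccentricity of each vertex, ``max_u d(v, u)``.
    diameter:
        ``max_v ecc(v)``.
    distance_multiplicity:
        ``k_i`` = number of unordered vertex pairs at distance ``i >= 1``
        (the value ``i`` appears ``2 k_i`` times in the distance matrix).
    distance_sum:
        ``DS(v) = sum_u d(v, u)``.
    """

    dist: dict[int, dict[int, int]]
    ecc: dict[int, int]
    diameter: int
    distance_multiplicity: dict[int, int]
    distance_sum: dict[int, int]

    @property
    def n(self) -> int:
        return len(self.dist)

    @property
    def wiener(self) -> int:
        return sum(i * k for i, k in self.distance_multiplicity.items())


def distance_index(g: LabeledGraph) -> DistanceIndex:
    """BFS hop distances and derived quantities for a connected graph."""
    dist = {v: dict(d) for v, d in nx.all_pairs_shortest_path_length(g.nx)}
    ecc = {v: max(row.values()) for v, row in dist.items()}
    diameter = max(ecc.values()) if ecc else 0
    mult: dict[int, int] = {}
    ds: dict[int, int] = {}
    verts = sorted(dist)
    for v in verts:
        ds[v] = sum(dist[v].values())
        for u in verts:
            if u > v:
                i = dist[v][u]
                mult[i] = mult.get(i, 0) + 1
    return DistanceIndex(dist, ecc, diameter, mult, ds)


class SphereTable:
    """j-spheres and label-restricted j-spheres of every vertex.

    ``sphere(v, j)`` is the set of vertices at distance exactly *j* from
    *v*; for ``1 <= j <= ecc(v)`` the spheres partition ``V \\ {v}``.
    ``label_sphere(v, j, l)`` restricts the sphere to vertices with vertex
    label *l*.
    """

    def __init__(self, g: LabeledGraph, d: DistanceIndex | None = None):
        d = d if d is not None else distance_index(g)
        self.index = d
        self._labels = g.vertex_labels
        self._spheres: dict[int, dict[int, set[int]]] = {}
        for v, row in d.dist.items():
            by_j: dict[int, set[int]] = {}
            for u, j in row.items():
                if j >= 1:
                    by_j.setdefault(j, set()).add(u)
            self._spheres[v] = by_j

    def sphere(self, v: int, j: int) -> set[int]:
        return self._spheres[v].get(j, set())

    def label_sphere(self, v: int, j: int, label: str) -> set[int]:
        return {u for u in self.sphere(v, j) if self._labels[u] == label}

    def sphere_sizes(self, v: int) -> dict[int, int]:
        """``{j: |S_j(v)|}`` for the non-empty spheres of *v*."""
        return {j: len(s) for j, s in self._spheres[v].items()}


class PathBudgetError(RuntimeError):
    """Total number of shortest paths exceeded the configured cap."""


@dataclass
class LocalInfoGraph:
    """Union of the shortest paths of length *j* starting at *center*.

    ``k`` counts those paths.  ``edge_multiplicity[e]`` is the number of the
    ``k`` paths that traverse edge *e*; ``vertex_set``/``edge_set`` are the
    unions over the paths.  Paths are directed away from the center, so a
    path and its reverse are never both counted.  The structure is stored
    implicitly as the depth-j slice of the BFS shortest-path DAG;
    :meth:`paths` enumerates the paths explicitly on demand.
    """

    center: int
    length: int
    k: int
    vertex_set: frozenset[int]
    edge_set: frozenset[tuple[int, int]]
    edge_multiplicity: dict[tuple[int, int], int]
    _succ: dict[int, tuple[int, ...]] = field(repr=False, default_factory=dict)

    def paths(self) -> Iterator[tuple[int, ...]]:
        """Explicitly enumerate the k shortest paths (vertex tuples)."""
        stack: list[tuple[int, ...]] = [(self.center,)]
        while stack:
            p = stack.pop()
            if len(p) == self.length + 1:
                yield p
                continue
            for w in self._succ.get(p[-1], ()):
                stack.append(p + (w,))


def local_info_graphs(
    g: LabeledGraph, v: int, max_paths: int = 10**6
) -> list[LocalInfoGraph]:
    """Local information graphs of *v* for every length ``j = 1..ecc(v)``.

    Uses the BFS shortest-path DAG rooted at *v*: the number of shortest
    paths of length *j* is obtained by counting path extensions down to
    depth *j*, and per-edge multiplicities come from combining upward path
    counts with downward extension counts.  Equivalent to explicit
    enumeration (which :meth:`LocalInfoGraph.paths` still provides), but
    polynomial even when the path count is large.

    Raises
    ------
    PathBudgetError
        if the total number of shortest paths across all j exceeds
        *max_paths*.
    """
    depth = nx.single_source_shortest_path_length(g.nx, v)
    ecc = max(depth.values())
    # shortest-path DAG: edge u -> w iff depth(w) = depth(u) + 1
    succ: dict[int, list[int]] = {u: [] for u in depth}
    for u, w in g.nx.edges:
        if depth[w] == depth[u] + 1:
            succ[u].append(w)
        elif depth[u] == depth[w] + 1:
            succ[w].append(u)
    # paths from v to each u along the DAG
    up: dict[int, int] = {v: 1}
    for u in sorted(depth, key=depth.get):
        for w in succ[u]:
            up[w] = up.get(w, 0) + up[u]

    by_depth: dict[int, list[int]] = {}
    for u, d in depth.items():
        by_depth.setdefault(d, []).append(u)

    out: list[LocalInfoGraph] = []
    total = 0
    for j in range(1, ecc + 1):
        # down[u] = number of DAG path extensions from u to depth j
        down: dict[int, int] = {}
        for d in range(j, -1, -1):
            for u in by_depth.get(d, []):
                if d == j:
                    down[u] = 1
                else:
                    down[u] = sum(down.get(w, 0) for w in succ[u])
        k = down.get(v, 0)
        total += k
        if total > max_paths:
            raise PathBudgetError(
                f"more than {max_paths} shortest paths from vertex {v}"
            )
        verts = frozenset(u for u in down if down[u] > 0)
        mult: dict[tuple[int, int], int] = {}
        succ_j: dict[int, tuple[int, ...]] = {}
        for u in verts:
            if depth[u] >= j:
                continue
            kept = tuple(w for w in succ[u] if down.get(w, 0) > 0)
            succ_j[u] = kept
            for w in kept:
                mult[(min(u, w), max(u, w))] = up[u] * down[w]
        out.append(
            LocalInfoGraph(
                center=v,
                length=j,
                k=k,
                vertex_set=verts,
                edge_set=frozenset(mult),
                edge_multiplicity=mult,
                _succ=succ_j,
            )
        )
    return out


def all_local_info_graphs(
    g: LabeledGraph, max_paths: int = 10**6
) -> dict[int, list[LocalInfoGraph]]:
    """Local information graphs for every vertex of *g*."""
    return {v: local_info_graphs(g, v, max_paths=max_paths) for v in g.vertices}
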