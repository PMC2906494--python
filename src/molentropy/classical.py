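"""Classical topological and information indices used for comparison.

Wiener index, cyclomatic number, the orbit-based topological information
content (entropy of the automorphism-orbit size distribution), and a set
of distance-based information indices computed from the distance matrix:

* ``I_D``   — entropy of the off-diagonal pair-distance distribution;
* ``I_D0``  — full-matrix variant including the n diagonal zeros;
* ``I_W``   — magnitude-based Wiener information,
  ``W log2 W - sum_i k_i i log2 i``;
* ``I_U``   — entropy of the distance-degree distribution
  ``DS(v) / 2W``;
* ``HV``    — mean per-vertex sphere-profile entropy (sphere sizes over n,
  including the trivial 0-sphere {v});
* ``HD``    — mean per-vertex distance-complexity entropy
  (``j |S_j(v)| / DS(v)`` terms).

Each index is an independently named, individually testable formula.
"""

from __future__ import annotations

import numpy as np

from .graph import LabeledGraph
from .metrics import DistanceIndex
from .entropy import shannon_entropy


def wiener(d: DistanceIndex) -> int:
    """Sum of shortest-path distances over unordered vertex pairs."""
    return d.wiener


def cyclomatic(g: LabeledGraph) -> int:
    """Number of independent cycles, ``|E| - |V| + 1`` (connected graph)."""
    return g.m - g.n + 1


class AutomorphismBudgetError(RuntimeError):
    """Graph too large for the exact automorphism-group computation."""


def automorphism_orbits(
    g: LabeledGraph, mode: str = "skeleton", max_vertices: int = 128
) -> list[frozenset[int]]:
    """Vertex orbits of the automorphism group.

    In ``"labeled"`` mode the vertex labels act as colours that
    automorphisms must preserve (so the labeled partition refines the
    skeleton partition); in ``"skeleton"`` mode labels are ignored.  The
    group itself is computed exactly with BLISS (colour-aware equitable
    refinement with backtracking) via igraph; orbits are the connected
    components of the vertex set under the returned generators.
    """
    import igraph as ig

    if g.n > max_vertices:
        raise AutomorphismBudgetError(
            f"|V| = {g.n} exceeds the automorphism budget of {max_vertices}"
        )
    if mode not in ("skeleton", "labeled"):
        raise ValueError(f"unknown mode {mode!r}")
    verts = g.vertices
    pos = {v: i for i, v in enumerate(verts)}
    graph = ig.Graph(
        n=len(verts), edges=[(pos[u], pos[v]) for u, v in g.edges]
    )
    color = None
    if mode == "labeled":
        codes = {lab: i for i, lab in enumerate(g.vertex_alphabet)}
        color = [codes[g.vertex_label(v)] for v in verts]
    generators = graph.automorphism_group(color=color)

    parent = list(range(len(verts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in generators:
        for i, j in enumerate(perm):
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i, v in enumerate(verts):
        groups.setdefault(find(i), set()).add(v)
    return sorted((frozenset(s) for s in groups.values()), key=lambda s: min(s))


def orbit_information(
    g: LabeledGraph, mode: str = "skeleton", max_vertices: int = 128
) -> float:
    """Topological information content: entropy of orbit sizes over n.

    Zero exactly when the graph is vertex-transitive (a single orbit).
    """
    orbits = automorphism_orbits(g, mode=mode, max_vertices=max_vertices)
    p = np.array([len(o) for o in orbits], dtype=float) / g.n
    return shannon_entropy(p)


def distance_information(d: DistanceIndex) -> dict[str, float]:
    """The six distance-matrix information indices (see module docstring)."""
    n = d.n
    if n < 2:
        raise ValueError("distance information indices need |V| >= 2")
    ks = d.distance_multiplicity
    t = n * (n - 1) // 2
    w = d.wiener

    p_pairs = np.array([k / t for k in ks.values()])
    i_d = shannon_entropy(p_pairs)

    # full matrix: n diagonal zeros plus 2 k_i occurrences of each value i
    p_full = np.concatenate(([n / n**2], [2 * k / n**2 for k in ks.values()]))
    i_d0 = shannon_entropy(p_full)

    i_w = w * np.log2(w) - sum(k * i * np.log2(i) for i, k in ks.items() if i > 1)

    ds = np.array([d.distance_sum[v] for v in sorted(d.distance_sum)], dtype=float)
    i_u = shannon_entropy(ds / (2 * w))

    hv = 0.0
    hd = 0.0
    for v, row in d.dist.items():
        sizes = np.bincount(list(row.values()))  # index 0 counts {v} itself
        present = np.nonzero(sizes)[0]
        hv += shannon_entropy(sizes[present] / n)
        js = present[present >= 1]
        terms = js * sizes[js] / d.distance_sum[v]
        hd += shannon_entropy(terms)
    hv /= n
    hd /= n

    return {
        "I_D": float(i_d),
        "I_D0": float(i_d0),
        "I_W": float(i_w),
        "I_U": float(i_u),
        "HV": float(hv),
        "HD": float(hd),
    }
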