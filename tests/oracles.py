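"""Independent brute-force oracles used only by the test suite.

These deliberately take the slow, obvious route (explicit enumeration,
factorial search, direct recomputation from the distance matrix) so the
package's polynomial algorithms can be checked against them on small
graphs.
"""

from collections import Counter
from itertools import permutations
from math import log2

import networkx as nx

from molentropy import LabeledGraph


def shortest_paths_by_length(g: LabeledGraph, v: int) -> dict[int, list[tuple[int, ...]]]:
    """All shortest paths starting at v, grouped by length, via networkx."""
    out: dict[int, list[tuple[int, ...]]] = {}
    for u in g.vertices:
        if u == v:
            continue
        for p in nx.all_shortest_paths(g.nx, v, u):
            out.setdefault(len(p) - 1, []).append(tuple(p))
    return out


def edge_functional_by_enumeration(g: LabeledGraph, edge_values, coeffs) -> dict[int, float]:
    """f^E by explicit path enumeration: sum_j b_j * sum_paths sum_e value(e)."""
    elab = g.edge_labels
    out = {}
    for v in g.vertices:
        total = 0.0
        for j, paths in shortest_paths_by_length(g, v).items():
            level = 0.0
            for p in paths:
                level += sum(
                    edge_values[elab[(min(a, b), max(a, b))]]
                    for a, b in zip(p, p[1:])
                )
            total += coeffs[j - 1] * level
        out[v] = total
    return out


def brute_orbits(g: LabeledGraph, labeled: bool = False) -> list[frozenset[int]]:
    """Automorphism orbits by factorial permutation search."""
    verts = g.vertices
    n = len(verts)
    pos = {v: i for i, v in enumerate(verts)}
    adj = {frozenset((pos[u], pos[v])) for u, v in g.edges}
    deg = [len(g.nx[verts[i]]) for i in range(n)]
    lab = [g.vertex_label(verts[i]) for i in range(n)]

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in permutations(range(n)):
        ok = True
        for i in range(n):
            if deg[i] != deg[perm[i]] or (labeled and lab[i] != lab[perm[i]]):
                ok = False
                break
        if not ok:
            continue
        if all(frozenset((perm[a], perm[b])) in adj for a, b in adj):
            for i in range(n):
                ri, rj = find(i), find(perm[i])
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(verts[i])
    return sorted((frozenset(s) for s in groups.values()), key=min)


def _entropy(probs) -> float:
    return -sum(p * log2(p) for p in probs if p > 0)


def distance_indices_from_matrix(g: LabeledGraph) -> dict[str, float]:
    """The six distance-information indices straight from the matrix."""
    d = dict(nx.floyd_warshall(g.nx))
    verts = g.vertices
    n = len(verts)
    pair_dists = [int(d[u][v]) for i, u in enumerate(verts) for v in verts[i + 1:]]
    t = len(pair_dists)
    counts = Counter(pair_dists)
    w = sum(pair_dists)
    ds = {v: sum(int(x) for x in d[v].values()) for v in verts}

    i_d = _entropy(c / t for c in counts.values())
    i_d0 = _entropy([n / n**2] + [2 * c / n**2 for c in counts.values()])
    i_w = w * log2(w) - sum(c * i * log2(i) for i, c in counts.items() if i > 1)
    i_u = _entropy(ds[v] / (2 * w) for v in verts)
    hv = 0.0
    hd = 0.0
    for v in verts:
        row = Counter(int(x) for x in d[v].values())
        hv += _entropy(c / n for c in row.values())
        hd += _entropy(j * c / ds[v] for j, c in row.items() if j >= 1)
    return {
        "I_D": i_d, "I_D0": i_d0, "I_W": i_w, "I_U": i_u,
        "HV": hv / n, "HD": hd / n,
    }


def is_isomorphic_brute(a: LabeledGraph, b: LabeledGraph, labeled: bool) -> bool:
    """Pairwise isomorphism by factorial search (tiny graphs only)."""
    if a.n != b.n or a.m != b.m:
        return False
    va, vb = a.vertices, b.vertices
    pa = {v: i for i, v in enumerate(va)}
    pb = {v: i for i, v in enumerate(vb)}
    ea = {frozenset((pa[u], pa[v])): a.edge_label(u, v) for u, v in a.edges}
    eb = {frozenset((pb[u], pb[v])): b.edge_label(u, v) for u, v in b.edges}
    la = [a.vertex_label(v) for v in va]
    lb = [b.vertex_label(v) for v in vb]
    for perm in permutations(range(len(vb))):
        if labeled and any(la[i] != lb[perm[i]] for i in range(len(va))):
            continue
        ok = True
        for e, lab in ea.items():
            i, j = tuple(e)
            img = frozenset((perm[i], perm[j]))
            if img not in eb or (labeled and eb[img] != lab):
                ok = False
                break
        if ok and len(ea) == len(eb):
            return True
    return False
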