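"""Information functionals: positive vertex weightings f(v).

Each functional assigns every vertex a strictly positive value; normalising
the values yields the vertex probability distribution whose Shannon entropy
is the graph's structural information content.  Four families are provided:

* :func:`f_sphere` — exponential in the j-sphere cardinalities (topology
  only);
* :func:`f_sphere_vlabel` — the same with per-atom-type weights inside each
  sphere (vertex labels);
* :func:`f_local_vlabel` — label occurrence counts inside the local
  information graphs, mixed with normalised per-label coefficients (vertex
  labels, no free exponent base);
* :func:`f_edge` — sphere-coefficient-weighted sums of shortest-path
  weights, where a path's weight adds up the numeric values of its bond
  labels (edge labels);

plus :func:`f_combined`, whose induced probability distribution is the
equal mixture of a vertex-label and an edge-label distribution.

Exponential functionals are handled in log space throughout, so graphs
whose sphere sums are large do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import LabeledGraph
from .metrics import LocalInfoGraph, SphereTable
from .schemes import CoefficientScheme


@dataclass(frozen=True)
class FunctionalValues:
    """Per-vertex functional values, kept as logarithms.

    ``log_values[i]`` is ``ln f(v)`` for ``vertices[i]``; :attr:`values`
    exponentiates on demand (may overflow to ``inf`` for extreme
    exponents — probabilities are always derived from the logs).
    """

    vertices: tuple[int, ...]
    log_values: np.ndarray
    name: str = "f"

    @classmethod
    def from_values(
        cls, vertices: tuple[int, ...], values, name: str = "f"
    ) -> "FunctionalValues":
        arr = np.asarray(values, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(f"functional {name!r} produced a non-positive value")
        return cls(vertices, np.log(arr), name)

    @property
    def values(self) -> np.ndarray:
        return np.exp(self.log_values)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.vertices, self.values))


def _truncate(sizes: dict[int, int], max_j: int | None) -> dict[int, int]:
    if max_j is None:
        return sizes
    return {j: s for j, s in sizes.items() if j <= max_j}


def f_sphere(
    g: LabeledGraph,
    spheres: SphereTable,
    scheme: CoefficientScheme,
    max_j: int | None = None,
) -> FunctionalValues:
    """Unlabeled sphere functional ``f(v) = alpha ** sum_j b_j |S_j(v)|``.

    *max_j* truncates the sum to the first *max_j* spheres (the
    sphere-approximation study); ``None`` keeps all spheres.
    """
    b = scheme.sphere_coefficients(spheres.index.diameter)
    ln_a = math.log(scheme.alpha)
    verts = tuple(sorted(spheres.index.dist))
    logs = np.empty(len(verts))
    for i, v in enumerate(verts):
        expo = sum(
            b[j - 1] * s for j, s in _truncate(spheres.sphere_sizes(v), max_j).items()
        )
        logs[i] = ln_a * expo
    return FunctionalValues(verts, logs, name="f_sphere")


def f_sphere_vlabel(
    g: LabeledGraph,
    spheres: SphereTable,
    scheme: CoefficientScheme,
    max_j: int | None = None,
) -> FunctionalValues:
    """Vertex-label sphere functional.

    ``f(v) = alpha ** sum_j sum_l b_j w(l) |S_j^l(v)|`` where ``S_j^l`` is
    the label-restricted sphere.  With uniform weights this reduces exactly
    to :func:`f_sphere`.
    """
    b = scheme.sphere_coefficients(spheres.index.diameter)
    ln_a = math.log(scheme.alpha)
    w = {lab: scheme.weight(lab) for lab in g.vertex_alphabet}
    labels = g.vertex_labels
    verts = tuple(sorted(spheres.index.dist))
    logs = np.empty(len(verts))
    for i, v in enumerate(verts):
        expo = 0.0
        for j in _truncate(spheres.sphere_sizes(v), max_j):
            for u in spheres.sphere(v, j):
                expo += b[j - 1] * w[labels[u]]
        logs[i] = ln_a * expo
    return FunctionalValues(verts, logs, name="f_sphere_vlabel")


def f_local_vlabel(
    g: LabeledGraph,
    ligs: dict[int, list[LocalInfoGraph]],
    scheme: CoefficientScheme,
    max_j: int | None = None,
    mix: dict[str, float] | None = None,
) -> FunctionalValues:
    """Vertex-label functional over local information graphs.

    With ``gamma_l(v, j)`` = number of vertices of the local information
    graph of (v, j) carrying label *l*,
    ``f(v) = sum_j sum_l c_l * gamma_l(v, j)``, the ``c_l`` being the
    normalised label-mix coefficients of the graph's alphabet.  An explicit
    *mix* mapping overrides the scheme's rule.
    """
    c = mix if mix is not None else scheme.mix_coefficients(g.vertex_alphabet)
    labels = g.vertex_labels
    verts = tuple(sorted(ligs))
    vals = np.empty(len(verts))
    for i, v in enumerate(verts):
        total = 0.0
        for lig in ligs[v]:
            if max_j is not None and lig.length > max_j:
                continue
            total += sum(c[labels[u]] for u in lig.vertex_set)
        vals[i] = total
    return FunctionalValues.from_values(verts, vals, name="f_local_vlabel")


def f_edge(
    g: LabeledGraph,
    ligs: dict[int, list[LocalInfoGraph]],
    scheme: CoefficientScheme,
    max_j: int | None = None,
) -> FunctionalValues:
    """Edge-label functional via weighted shortest paths.

    A path's weight is the sum of the numeric values of its edge labels;
    ``L_j(v)`` sums the weights of the k_j shortest paths of length j from
    v, and ``f^E(v) = sum_j b_j L_j(v)``.  ``L_j`` is evaluated from the
    per-edge path multiplicities of the local information graph, which
    equals explicit path enumeration.
    """
    rho = max(lig.length for lst in ligs.values() for lig in lst) if ligs else 0
    b = scheme.sphere_coefficients(rho)
    ev = {lab: scheme.edge_value(lab) for lab in g.edge_alphabet}
    elabel = g.edge_labels
    verts = tuple(sorted(ligs))
    vals = np.empty(len(verts))
    for i, v in enumerate(verts):
        total = 0.0
        for lig in ligs[v]:
            if max_j is not None and lig.length > max_j:
                continue
            level = sum(
                mult * ev[elabel[e]] for e, mult in lig.edge_multiplicity.items()
            )
            total += b[lig.length - 1] * level
        vals[i] = total
    return FunctionalValues.from_values(verts, vals, name="f_edge")


def f_combined(fv: FunctionalValues, fe: FunctionalValues) -> FunctionalValues:
    """Equal mixture of the distributions induced by two functionals.

    The returned values are the mixture probabilities themselves, so the
    induced distribution is ``p = (p_fv + p_fe) / 2`` exactly, independent
    of the scales of the ingredients.
    """
    if fv.vertices != fe.vertices:
        raise ValueError("functionals are defined on different vertex sets")
    from .entropy import _softmax  # local import to avoid a cycle

    p = (_softmax(fv.log_values) + _softmax(fe.log_values)) / 2.0
    return FunctionalValues.from_values(fv.vertices, p, name="f_combined")
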