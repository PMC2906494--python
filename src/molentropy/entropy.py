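"""Vertex probabilities, graph entropy and the lambda-measure family.

A functional f induces ``p(v) = f(v) / sum_u f(u)``; the graph entropy is
the Shannon entropy (base 2, bits) of this distribution, and the
lambda-measure is ``lam * (log2 |V| - entropy)`` — zero exactly at maximum
entropy, growing as the distribution departs from uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .graph import LabeledGraph
from .metrics import SphereTable, all_local_info_graphs
from .functionals import (
    FunctionalValues,
    f_edge,
    f_local_vlabel,
    f_sphere,
    f_sphere_vlabel,
)
from .schemes import CoefficientScheme


@dataclass(frozen=True)
class EntropyValue:
    """Entropy (bits), lambda-measure and the underlying distribution."""

    entropy: float
    lambda_measure: float
    probabilities: dict[int, float]
    measure_name: str = ""


def _softmax(log_values: np.ndarray) -> np.ndarray:
    z = np.exp(log_values - np.max(log_values))
    return z / z.sum()


def vertex_probabilities(f: FunctionalValues) -> dict[int, float]:
    """``p(v) = f(v) / sum f`` computed stably from the log values."""
    return dict(zip(f.vertices, _softmax(f.log_values)))


def shannon_entropy(p: np.ndarray) -> float:
    """Base-2 Shannon entropy with the convention ``0 * log 0 = 0``."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def graph_entropy(f: FunctionalValues, scheme: CoefficientScheme) -> EntropyValue:
    """Entropy of the distribution induced by *f*, plus its lambda-measure."""
    p = _softmax(f.log_values)
    h = shannon_entropy(p)
    lam = scheme.lam * (np.log2(len(p)) - h)
    return EntropyValue(
        entropy=h,
        lambda_measure=float(lam),
        probabilities=dict(zip(f.vertices, p)),
        measure_name=f.name,
    )


#: functional kinds accepted by :func:`truncated_entropy`
FUNCTIONAL_KINDS = ("sphere", "sphere_vlabel", "local_vlabel", "edge")


def compute_functional(
    g: LabeledGraph,
    scheme: CoefficientScheme,
    kind: str,
    max_j: int | None = None,
    spheres: SphereTable | None = None,
    ligs=None,
) -> FunctionalValues:
    """Evaluate one of the named functionals on *g* (optionally truncated)."""
    if kind in ("sphere", "sphere_vlabel"):
        spheres = spheres if spheres is not None else SphereTable(g)
        fn = f_sphere if kind == "sphere" else f_sphere_vlabel
        return fn(g, spheres, scheme, max_j=max_j)
    if kind in ("local_vlabel", "edge"):
        ligs = ligs if ligs is not None else all_local_info_graphs(g)
        fn = f_local_vlabel if kind == "local_vlabel" else f_edge
        return fn(g, ligs, scheme, max_j=max_j)
    raise ValueError(f"unknown functional kind {kind!r}; choose from {FUNCTIONAL_KINDS}")


def truncated_entropy(
    g: LabeledGraph,
    scheme: CoefficientScheme,
    functional_kind: str,
    k: int,
) -> EntropyValue:
    """Sphere-truncated entropy: drop every sphere/level term with j > k.

    For ``k >= diameter`` this equals the untruncated measure exactly; the
    sequence over k quantifies how much structural information the first k
    neighbourhood shells already carry.
    """
    if k < 1:
        raise ValueError("truncation level k must be >= 1")
    f = compute_functional(g, scheme, functional_kind, max_j=k)
    return graph_entropy(f, scheme)


def entropy_cdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of a descriptor sample: sorted values, percentile ranks."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    ranks = np.arange(1, v.size + 1) / v.size
    return v, ranks


def cdf_sup_distance(a, b) -> float:
    """Sup-distance (two-sample KS statistic) between two empirical CDFs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(ks_2samp(a, b, method="asymp").statistic)
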