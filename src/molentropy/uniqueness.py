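"""Corpus deduplication and descriptor discrimination power.

A descriptor is *degenerate* on a corpus when two non-isomorphic graphs
receive the same value.  The sensitivity index S(I) is the fraction of
graphs whose value of index I is unique in the corpus — 1 for a perfectly
discriminating index, 0 when the index is constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .graph import LabeledGraph, to_skeleton


@dataclass(frozen=True)
class SensitivityReport:
    """Degeneracy summary of one descriptor over a corpus."""

    index_name: str
    n_graphs: int
    n_degenerate: int
    sensitivity: float
    value_tolerance: float


def dedup_isomorphic(
    graphs: Sequence[LabeledGraph], mode: str = "skeleton"
) -> list[LabeledGraph]:
    """Keep one representative per isomorphism class, first occurrence wins.

    ``mode="labeled"`` treats vertex and edge labels as colours that must
    match; ``mode="skeleton"`` compares topology only.  Candidates are
    bucketed by Weisfeiler-Lehman hash and confirmed by exact (VF2)
    isomorphism inside each bucket, so the result is exact.
    """
    if mode not in ("skeleton", "labeled"):
        raise ValueError(f"unknown mode {mode!r}")
    node_match = edge_match = None
    if mode == "labeled":
        node_match = nxiso.categorical_node_match("label", None)
        edge_match = nxiso.categorical_edge_match("label", None)

    buckets: dict[str, list[LabeledGraph]] = {}
    kept: list[LabeledGraph] = []
    for g in graphs:
        h = to_skeleton(g) if mode == "skeleton" else g
        key = "%d|%d|%s" % (
            g.n,
            g.m,
            nx.weisfeiler_lehman_graph_hash(
                h.nx,
                node_attr="label" if mode == "labeled" else None,
                edge_attr="label" if mode == "labeled" else None,
            ),
        )
        bucket = buckets.setdefault(key, [])
        target = h.nx
        duplicate = False
        for rep_h in bucket:
            if nx.is_isomorphic(
                rep_h.nx, target, node_match=node_match, edge_match=edge_match
            ):
                duplicate = True
                break
        if not duplicate:
            bucket.append(h)
            kept.append(g)
    return kept


def sensitivity_index(
    values: Mapping[object, float],
    tolerance: float = 1e-9,
    exact: bool = False,
    name: str = "",
) -> SensitivityReport:
    """Sensitivity S(I) = (|G| - N_I) / |G| of a descriptor over a corpus.

    ``N_I`` counts graphs whose value coincides with at least one other
    graph's value.  Coincidence is relative-tolerance equality (default
    1e-9) unless *exact* is set, which is appropriate for integer-valued
    indices such as the Wiener index.
    """
    if not values:
        raise ValueError("empty corpus")
    items = sorted(values.items(), key=lambda kv: kv[1])
    n = len(items)
    degenerate = [False] * n
    for i in range(n - 1):
        a, b = items[i][1], items[i + 1][1]
        if exact:
            close = a == b
        else:
            close = abs(b - a) <= tolerance * max(abs(a), abs(b), 1e-300)
        if close:
            degenerate[i] = degenerate[i + 1] = True
    n_deg = sum(degenerate)
    return SensitivityReport(
        index_name=name,
        n_graphs=n,
        n_degenerate=n_deg,
        sensitivity=(n - n_deg) / n,
        value_tolerance=0.0 if exact else tolerance,
    )
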