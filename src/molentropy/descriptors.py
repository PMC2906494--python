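"""Named descriptors and superindex construction.

A *superindex* is the concatenation of several topological indices into
one feature vector per graph.  The default 16-descriptor set pairs eleven
unlabeled-graph measures (entropy descriptors on the skeleton plus
classical distance/orbit indices) with five labeled-graph entropy
descriptors:

unlabeled: ``I_fV_lin, I_fV_exp, Ilam_fV_lin, I_orb, I_D, I_D0, W, I_W,
I_U, HV, HD``
labeled:   ``I_fVhat_mass, I_fVhat_invmass, I_fDV_lin, I_fDV_exp, I_fE``

Descriptor names follow the measures they evaluate: ``I_fV`` — entropy of
the unlabeled sphere functional (linear/exponential sphere coefficients);
``Ilam_`` — the corresponding lambda-measure; ``I_fVhat`` — the
vertex-label sphere functional with atomic-mass or inverse-mass weights;
``I_fDV`` — the local-information-graph label functional with
linear-rank/exponential-rank label mixing; ``I_fE`` — the edge functional;
``I_fVE`` — the combined vertex+edge measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import LabeledGraph
from .metrics import SphereTable, all_local_info_graphs
from .schemes import CoefficientScheme
from .functionals import f_combined, f_edge, f_local_vlabel, f_sphere, f_sphere_vlabel
from .entropy import graph_entropy
from .classical import cyclomatic, distance_information, orbit_information, wiener


class _GraphContext:
    """Caches the per-graph intermediates shared by several descriptors."""

    def __init__(self, g: LabeledGraph, scheme: CoefficientScheme):
        self.g = g
        self.scheme = scheme
        self._spheres = None
        self._ligs = None
        self._dinfo = None

    @property
    def spheres(self) -> SphereTable:
        if self._spheres is None:
            self._spheres = SphereTable(self.g)
        return self._spheres

    @property
    def ligs(self):
        if self._ligs is None:
            self._ligs = all_local_info_graphs(self.g)
        return self._ligs

    @property
    def dinfo(self) -> dict[str, float]:
        if self._dinfo is None:
            self._dinfo = distance_information(self.spheres.index)
        return self._dinfo


def _entropy_of(ctx: _GraphContext, kind: str, scheme: CoefficientScheme, lam: bool):
    g = ctx.g
    if kind == "sphere":
        f = f_sphere(g, ctx.spheres, scheme)
    elif kind == "sphere_vlabel":
        f = f_sphere_vlabel(g, ctx.spheres, scheme)
    elif kind == "local_vlabel":
        f = f_local_vlabel(g, ctx.ligs, scheme)
    elif kind == "edge":
        f = f_edge(g, ctx.ligs, scheme)
    elif kind == "combined":
        f = f_combined(
            f_sphere_vlabel(g, ctx.spheres, scheme), f_edge(g, ctx.ligs, scheme)
        )
    else:  # pragma: no cover - registry is closed
        raise ValueError(kind)
    ev = graph_entropy(f, scheme)
    return ev.lambda_measure if lam else ev.entropy


def _reg() -> dict[str, tuple[str, Callable[[_GraphContext], float]]]:
    r: dict[str, tuple[str, Callable[[_GraphContext], float]]] = {}

    def ent(kind, lam=False, **over):
        def compute(ctx: _GraphContext, _kind=kind, _lam=lam, _over=over):
            scheme = ctx.scheme.with_(**_over) if _over else ctx.scheme
            return _entropy_of(ctx, _kind, scheme, _lam)

        return compute

    # unlabeled entropy descriptors (evaluated on topology only)
    r["I_fV_lin"] = ("unlabeled", ent("sphere", sphere_coeffs="linear"))
    r["I_fV_exp"] = ("unlabeled", ent("sphere", sphere_coeffs="exponential"))
    r["Ilam_fV_lin"] = ("unlabeled", ent("sphere", lam=True, sphere_coeffs="linear"))
    r["Ilam_fV_exp"] = ("unlabeled", ent("sphere", lam=True, sphere_coeffs="exponential"))
    # classical comparison indices
    r["I_orb"] = ("unlabeled", lambda c: orbit_information(c.g, mode="skeleton"))
    r["W"] = ("unlabeled", lambda c: float(wiener(c.spheres.index)))
    r["mu"] = ("unlabeled", lambda c: float(cyclomatic(c.g)))
    for key in ("I_D", "I_D0", "I_W", "I_U", "HV", "HD"):
        r[key] = ("unlabeled", lambda c, k=key: c.dinfo[k])
    # labeled entropy descriptors
    r["I_fVhat_mass"] = ("labeled", ent("sphere_vlabel", label_weight="mass"))
    r["I_fVhat_invmass"] = ("labeled", ent("sphere_vlabel", label_weight="inverse_mass"))
    r["Ilam_fVhat_mass"] = ("labeled", ent("sphere_vlabel", lam=True, label_weight="mass"))
    r["Ilam_fVhat_invmass"] = (
        "labeled",
        ent("sphere_vlabel", lam=True, label_weight="inverse_mass"),
    )
    r["I_fDV_lin"] = ("labeled", ent("local_vlabel", label_mix="linear_rank"))
    r["I_fDV_exp"] = ("labeled", ent("local_vlabel", label_mix="exponential_rank"))
    r["Ilam_fDV_lin"] = ("labeled", ent("local_vlabel", lam=True, label_mix="linear_rank"))
    r["Ilam_fDV_exp"] = (
        "labeled",
        ent("local_vlabel", lam=True, label_mix="exponential_rank"),
    )
    r["I_fE"] = ("labeled", ent("edge"))
    r["Ilam_fE"] = ("labeled", ent("edge", lam=True))
    r["I_fVE"] = ("labeled", ent("combined"))
    r["Ilam_fVE"] = ("labeled", ent("combined", lam=True))
    return r


REGISTRY = _reg()

#: group tag ("unlabeled" / "labeled") for every known descriptor
FEATURE_GROUPS: dict[str, str] = {name: grp for name, (grp, _) in REGISTRY.items()}

#: default superindex: 11 unlabeled + 5 labeled descriptors
DEFAULT_SUPERINDEX: tuple[str, ...] = (
    "I_fV_lin", "I_fV_exp", "Ilam_fV_lin", "I_orb", "I_D", "I_D0",
    "W", "I_W", "I_U", "HV", "HD",
    "I_fVhat_mass", "I_fVhat_invmass", "I_fDV_lin", "I_fDV_exp", "I_fE",
)


@dataclass
class DescriptorTable:
    """Per-graph descriptor matrix plus optional binary class labels."""

    frame: pd.DataFrame
    labels: pd.Series | None = None
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def features_in_group(self, group: str) -> list[str]:
        return [c for c in self.frame.columns if self.groups.get(c) == group]

    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        cols = list(features) if features is not None else self.feature_names
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table has no class labels")
        return self.labels.to_numpy(dtype=int)

    def select(self, features: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(
            self.frame[list(features)].copy(),
            None if self.labels is None else self.labels.copy(),
            {c: self.groups[c] for c in features if c in self.groups},
        )


def compute_descriptors(
    g: LabeledGraph,
    scheme: CoefficientScheme | None = None,
    names: Sequence[str] = DEFAULT_SUPERINDEX,
) -> dict[str, float]:
    """Evaluate the named descriptors on one graph."""
    scheme = scheme if scheme is not None else CoefficientScheme()
    ctx = _GraphContext(g, scheme)
    out: dict[str, float] = {}
    for name in names:
        if name not in REGISTRY:
            raise KeyError(f"unknown descriptor {name!r}")
        out[name] = float(REGISTRY[name][1](ctx))
    return out


def build_superindex(
    graphs: Sequence[LabeledGraph],
    scheme: CoefficientScheme | None = None,
    feature_set: Sequence[str] = DEFAULT_SUPERINDEX,
    labels: Iterable[int] | None = None,
) -> DescriptorTable:
    """Descriptor table (superindex vectors) for a corpus of graphs."""
    scheme = scheme if scheme is not None else CoefficientScheme()
    names = [g.name or f"g{i}" for i, g in enumerate(graphs)]
    rows = [compute_descriptors(g, scheme, feature_set) for g in graphs]
    frame = pd.DataFrame(rows, index=pd.Index(names, name="graph"))
    lab = None
    if labels is not None:
        lab = pd.Series(list(labels), index=frame.index, name="class").astype(int)
        if not set(lab.unique()) <= {0, 1}:
            raise ValueError("class labels must be binary 0/1")
    groups = {c: FEATURE_GROUPS[c] for c in frame.columns}
    return DescriptorTable(frame, lab, groups)
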