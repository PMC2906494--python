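"""Synthetic labeled-graph generators.

Everything in the package is testable without external chemical data:
labeled cycles along a controlled disorder axis (uniform -> blocks ->
alternating -> all-distinct label configurations), random connected
molecule-like graphs (degree capped at four, atom types from a weighted
alphabet, bond types single/double), and a two-class corpus in which the
class signal lives in the *label configuration* while topologies are
matched across classes — so labeled-graph descriptors carry the signal and
unlabeled ones do not.
"""

from __future__ import annotations

import numpy as np

from .graph import LabeledGraph

#: default atom alphabet for cycle fixtures (organic elements first)
CYCLE_ALPHABET = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
    "Si", "Se", "As", "Sn", "Ti", "Fe", "Cu", "Zn", "Ag", "Au",
)

#: weighted atom alphabet of the random-molecule generator (organic bias)
MOLECULE_ALPHABET = ("C", "N", "O", "S")
MOLECULE_WEIGHTS = (0.7, 0.12, 0.12, 0.06)


def make_labeled_cycle(
    n: int,
    label_configuration: str = "uniform",
    edge_configuration: str = "uniform",
    alphabet: tuple[str, ...] = CYCLE_ALPHABET,
) -> LabeledGraph:
    """Cycle C_n with a prescribed label disorder pattern.

    ``uniform``: one label for all vertices; ``blocks``: two contiguous
    halves with different labels; ``alternating``: two labels alternating
    (even n only — an odd cycle breaks the pattern and is rejected);
    ``all_distinct``: n pairwise distinct labels (needs n <= |alphabet|).
    Edge configuration ``uniform`` makes every bond single; ``mixed``
    alternates single/double bonds.
    """
    if n < 3:
        raise ValueError("a cycle needs n >= 3")
    if label_configuration == "uniform":
        labels = [alphabet[0]] * n
    elif label_configuration == "blocks":
        half = n // 2
        labels = [alphabet[0]] * half + [alphabet[1]] * (n - half)
    elif label_configuration == "alternating":
        if n % 2:
            raise ValueError("alternating labels need an even cycle length")
        labels = [alphabet[i % 2] for i in range(n)]
    elif label_configuration == "all_distinct":
        if n > len(alphabet):
            raise ValueError(f"all_distinct needs n <= {len(alphabet)} labels")
        labels = list(alphabet[:n])
    else:
        raise ValueError(f"unknown label_configuration {label_configuration!r}")

    if edge_configuration == "uniform":
        elabs = ["s"] * n
    elif edge_configuration == "mixed":
        elabs = [("s", "d")[i % 2] for i in range(n)]
    else:
        raise ValueError(f"unknown edge_configuration {edge_configuration!r}")

    edges = [(i, (i + 1) % n, elabs[i]) for i in range(n)]
    return LabeledGraph.from_labels(
        labels, edges, name=f"C{n}_{label_configuration}_{edge_configuration}"
    )


def make_random_molecule(
    n: int,
    alphabet: tuple[str, ...] = MOLECULE_ALPHABET,
    seed: int | np.random.Generator = 0,
    label_weights: tuple[float, ...] | None = None,
    double_bond_prob: float = 0.15,
    extra_edge_prob: float = 0.15,
    name: str = "",
) -> LabeledGraph:
    """Random connected molecule-like graph with maximum degree 4.

    A random attachment tree (respecting the degree cap) is decorated with
    a few extra ring-closing edges; atom types are drawn from the weighted
    alphabet, bond types from {single, double}.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if label_weights is None:
        label_weights = MOLECULE_WEIGHTS if alphabet == MOLECULE_ALPHABET else None
    labels = list(rng.choice(alphabet, size=n, p=label_weights))

    deg = [0] * n
    edges: list[tuple[int, int, str]] = []
    present: set[tuple[int, int]] = set()

    def bond() -> str:
        return "d" if rng.random() < double_bond_prob else "s"

    for v in range(1, n):
        candidates = [u for u in range(v) if deg[u] < 4]
        u = int(rng.choice(candidates))
        edges.append((u, v, bond()))
        present.add((u, v))
        deg[u] += 1
        deg[v] += 1
    # ring closures
    n_extra = rng.binomial(max(n - 3, 0), extra_edge_prob) if n >= 4 else 0
    for _ in range(int(n_extra)):
        open_v = [v for v in range(n) if deg[v] < 4]
        if len(open_v) < 2:
            break
        u, v = rng.choice(open_v, size=2, replace=False)
        u, v = int(min(u, v)), int(max(u, v))
        if u == v or (u, v) in present:
            continue
        edges.append((u, v, bond()))
        present.add((u, v))
        deg[u] += 1
        deg[v] += 1
    return LabeledGraph.from_labels(labels, edges, name=name or f"mol{n}")


#: disordered-class alphabet of the two-class generator
DISORDER_ALPHABET = ("C", "N", "O", "S", "P", "F", "Cl")


def make_two_class_dataset(
    n_graphs: int = 400,
    seed: int = 0,
    n_range: tuple[int, int] = (8, 20),
    hetero_prob: float = 0.1,
    double_bond_prob_disordered: float = 0.5,
) -> tuple[list[LabeledGraph], np.ndarray]:
    """Topology-matched two-class corpus with a label-disorder signal.

    Graphs come in pairs sharing one random topology.  The class-0 member
    gets an ordered labeling (carbon skeleton with occasional heteroatoms,
    single bonds); the class-1 member gets a disordered labeling (atom
    types uniform over a 7-element alphabet, bond types mixed
    single/double).  Because topologies are identical across classes,
    unlabeled descriptors carry no class signal by construction while
    labeled descriptors do — shuffling the class labels destroys it.
    """
    if n_graphs < 20:
        raise ValueError("need n_graphs >= 20")
    rng = np.random.default_rng(seed)
    graphs: list[LabeledGraph] = []
    labels: list[int] = []
    n_pairs = n_graphs // 2
    for i in range(n_pairs):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        topo = make_random_molecule(n, seed=rng, name=f"pair{i}")
        edges = topo.edges

        ordered_labels = [
            "N" if rng.random() < hetero_prob else "C" for _ in range(n)
        ]
        g0 = LabeledGraph.from_labels(
            ordered_labels, [(u, v, "s") for u, v in edges], name=f"pair{i}_ordered"
        )
        disordered_labels = list(rng.choice(DISORDER_ALPHABET, size=n))
        g1 = LabeledGraph.from_labels(
            disordered_labels,
            [
                (u, v, "d" if rng.random() < double_bond_prob_disordered else "s")
                for u, v in edges
            ],
            name=f"pair{i}_disordered",
        )
        graphs.extend([g0, g1])
        labels.extend([0, 1])
    order = rng.permutation(len(graphs))
    graphs = [graphs[i] for i in order]
    y = np.array([labels[i] for i in order], dtype=int)
    return graphs, y
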