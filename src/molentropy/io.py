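"""Chemical structure I/O.

V2000 Molfile/SDF and SMILES input are parsed with RDKit and converted to
:class:`~molentropy.graph.LabeledGraph`: element symbols become vertex
labels, bond orders become edge labels (1 -> "s", 2 -> "d", 3 -> "t",
aromatic -> "ar").  Hydrogen handling and salt (multi-fragment) handling
are explicit policies.  Descriptor tables are written/read as plain TSV.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, TextIO

import networkx as nx
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .graph import GraphError, LabeledGraph

RDLogger.DisableLog("rdApp.*")  # rdkit warnings are not actionable here

BOND_SYMBOL = {
    Chem.BondType.SINGLE: "s",
    Chem.BondType.DOUBLE: "d",
    Chem.BondType.TRIPLE: "t",
    Chem.BondType.AROMATIC: "ar",
}
BOND_TYPE = {v: k for k, v in BOND_SYMBOL.items()}


class ParseError(ValueError):
    """Malformed or unsupported structure input."""


def _mol_to_graph(
    mol: Chem.Mol, hydrogen_policy: str, fragment_policy: str, name: str
) -> LabeledGraph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), label=atom.GetSymbol())
    for bond in mol.GetBonds():
        sym = BOND_SYMBOL.get(bond.GetBondType())
        if sym is None:
            raise ParseError(
                f"{name or 'record'}: unsupported bond type {bond.GetBondType()}"
            )
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), label=sym)

    if hydrogen_policy == "suppress":
        g.remove_nodes_from([v for v, d in g.nodes(data=True) if d["label"] == "H"])
        if g.number_of_nodes() == 0:
            raise ParseError(f"{name or 'record'}: no heavy atoms after H suppression")
    elif hydrogen_policy != "keep":
        raise ValueError(f"unknown hydrogen_policy {hydrogen_policy!r}")

    if not nx.is_connected(g):
        if fragment_policy == "reject":
            raise ParseError(f"{name or 'record'}: disconnected structure (salt?)")
        if fragment_policy == "largest":
            keep = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
            g = g.subgraph(keep).copy()
        else:
            raise ValueError(f"unknown fragment_policy {fragment_policy!r}")

    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    return LabeledGraph(g, name=name)


def read_sdf(
    stream: TextIO | str,
    hydrogen_policy: str = "suppress",
    fragment_policy: str = "reject",
) -> list[LabeledGraph]:
    """Parse a V2000 Molfile/SDF text stream into labeled graphs.

    Records are read without valence sanitisation, so the connection table
    is transcribed as written.  ``hydrogen_policy="suppress"`` removes
    explicit hydrogens (the default: descriptor work uses heavy-atom
    graphs); ``fragment_policy`` decides whether disconnected records are
    an error (``"reject"``) or reduced to their largest component
    (``"largest"``).
    """
    text = stream if isinstance(stream, str) else stream.read()
    out: list[LabeledGraph] = []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"SDF record {i + 1} could not be parsed")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{i + 1}"
        out.append(_mol_to_graph(mol, hydrogen_policy, fragment_policy, name))
    return out


def read_smiles(
    strings: Iterable[str],
    hydrogen_policy: str = "suppress",
    fragment_policy: str = "reject",
) -> list[LabeledGraph]:
    """Parse SMILES strings; yields the same graphs as the equivalent SDF."""
    out: list[LabeledGraph] = []
    for i, smi in enumerate(strings):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"unparsable SMILES {smi!r}")
        if hydrogen_policy == "keep":
            mol = Chem.AddHs(mol)
        out.append(_mol_to_graph(mol, hydrogen_policy, fragment_policy, smi))
    return out


def write_sdf(graphs: Iterable[LabeledGraph], stream: TextIO | None = None) -> str:
    """Write labeled graphs as V2000 SDF; returns the text (and writes it)."""
    buf = _io.StringIO()
    for g in graphs:
        mol = Chem.RWMol()
        order = g.vertices
        pos = {}
        for v in order:
            lab = g.vertex_label(v)
            pos[v] = mol.AddAtom(Chem.Atom(lab if lab.isalpha() else "C"))
        for u, v in g.edges:
            mol.AddBond(pos[u], pos[v], BOND_TYPE.get(g.edge_label(u, v), Chem.BondType.SINGLE))
        m = mol.GetMol()
        m.SetProp("_Name", g.name or "")
        for atom in m.GetAtoms():
            atom.SetNoImplicit(True)
        buf.write(Chem.MolToMolBlock(m, kekulize=False))
        buf.write("$$$$\n")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def write_table(frame: pd.DataFrame, stream: TextIO) -> None:
    """Write a descriptor table as TSV, floats at 12 significant digits."""
    if frame.columns.duplicated().any():
        raise ValueError("descriptor table has duplicate column names")
    frame.to_csv(stream, sep="\t", float_format="%.12g", index=True, index_label="graph")


def read_table(stream: TextIO | str) -> pd.DataFrame:
    """Read a TSV descriptor table written by :func:`write_table`.

    Numeric columns come back as float64 (descriptor values are real even
    when a particular index, like the Wiener index, is integer-valued).
    """
    frame = pd.read_csv(stream, sep="\t", index_col="graph")
    for c in frame.columns:
        if pd.api.types.is_numeric_dtype(frame[c]):
            frame[c] = frame[c].astype(float)
    return frame
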