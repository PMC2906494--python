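"""Structure parsing, skeletons and descriptor-table round trips."""

import io

import numpy as np
import pandas as pd
import pytest

import molentropy as me
from conftest import random_labeled_graph

ACETONE_FRAGMENT_SDF = """propanone-fragment
  hand 2D

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    0.0000    0.0000    0.0000 O   0  0
    0.0000    0.0000    0.0000 C   0  0
  1  2  2  0
  1  3  1  0
M  END
$$$$
"""

SINGLE_ATOM_SDF = """methane-heavy-atom


  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
M  END
$$$$
"""


def test_read_sdf_transcribes_connection_table():
    (g,) = me.read_sdf(ACETONE_FRAGMENT_SDF)
    assert g.n == 3 and g.m == 2
    assert sorted(g.vertex_labels.values()) == ["C", "C", "O"]
    assert sorted(g.edge_labels.values()) == ["d", "s"]


def test_read_sdf_single_atom_record():
    (g,) = me.read_sdf(SINGLE_ATOM_SDF)
    assert g.n == 1 and g.m == 0


def test_hydrogen_suppression_of_explicit_h():
    # ethane with all hydrogens explicit, written out and re-read suppressed
    (full,) = me.read_smiles(["CC"], hydrogen_policy="keep")
    assert full.n == 8
    sdf = me.write_sdf([full])
    (heavy,) = me.read_sdf(sdf, hydrogen_policy="suppress")
    assert heavy.n == 2 and heavy.m == 1
    assert list(heavy.edge_labels.values()) == ["s"]


@pytest.mark.parametrize(
    "smiles, n, m, elabels",
    [
        ("CC", 2, 1, ["s"]),
        ("O=C", 2, 1, ["d"]),
        ("C1CCCCC1", 6, 6, ["s"] * 6),
    ],
)
def test_read_smiles_examples(smiles, n, m, elabels):
    (g,) = me.read_smiles([smiles])
    assert g.n == n and g.m == m
    assert sorted(g.edge_labels.values()) == sorted(elabels)
    if smiles == "C1CCCCC1":
        assert all(lab == "C" for lab in g.vertex_labels.values())
        assert sorted(d for _, d in g.nx.degree) == [2] * 6


def test_read_smiles_rejects_garbage():
    with pytest.raises(me.ParseError):
        me.read_smiles(["not-a-molecule(("])


def test_fragment_policies():
    with pytest.raises(me.ParseError):
        me.read_smiles(["CC.O"], fragment_policy="reject")
    (g,) = me.read_smiles(["CC.O"], fragment_policy="largest")
    assert g.n == 2 and sorted(g.vertex_labels.values()) == ["C", "C"]


def test_skeleton_erases_labels_and_is_idempotent(coc):
    s = me.to_skeleton(coc)
    assert set(s.vertex_labels.values()) == {"*"}
    assert set(s.edge_labels.values()) == {"-"}
    assert s.edges == coc.edges
    s2 = me.to_skeleton(s)
    assert s2.vertex_labels == s.vertex_labels and s2.edges == s.edges


def test_sdf_round_trip_preserves_topology_and_labels():
    rng = np.random.default_rng(11)
    graphs = [me.make_random_molecule(int(rng.integers(2, 15)), seed=rng) for _ in range(20)]
    back = me.read_sdf(me.write_sdf(graphs))
    for a, b in zip(graphs, back):
        assert a.n == b.n and a.edges == b.edges
        assert a.vertex_labels == b.vertex_labels
        assert a.edge_labels == b.edge_labels


def test_table_round_trip_and_shape():
    frame = pd.DataFrame(
        {"A": [1.0, 2.123456789012345], "B": [0.5, -3.25], "C": [4.0, 5.0]},
        index=pd.Index(["g1", "g2"], name="graph"),
    )
    buf = io.StringIO()
    me.write_table(frame, buf)
    text = buf.getvalue()
    assert len(text.splitlines()) == 3  # header + 2 graphs
    back = me.read_table(io.StringIO(text))
    pd.testing.assert_frame_equal(back, frame, rtol=1e-11)  # 12 sig digits

    empty = pd.DataFrame(columns=["A", "B"], index=pd.Index([], name="graph"))
    buf = io.StringIO()
    me.write_table(empty, buf)
    assert len(buf.getvalue().splitlines()) == 1  # header only


def test_invalid_graphs_rejected():
    with pytest.raises(me.GraphError):
        me.LabeledGraph.from_labels(["C", "C"], [])  # disconnected
    with pytest.raises(me.GraphError):
        me.LabeledGraph.from_labels(["C"], [(0, 0, "s")])  # loop


def test_random_graph_fixture_valid():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = random_labeled_graph(rng, int(rng.integers(2, 8)))
        assert g.n >= 2
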