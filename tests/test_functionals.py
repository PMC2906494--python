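"""Information functionals: hand-evaluated cases and structural properties."""

import numpy as np
import pytest

import molentropy as me
from conftest import random_labeled_graph
from oracles import edge_functional_by_enumeration

LIN2 = me.CoefficientScheme(alpha=2.0, sphere_coeffs="linear")  # b=(2,1) at rho=2


def test_f_sphere_hand_path(path3):
    f = me.f_sphere(path3, me.SphereTable(path3), LIN2)
    np.testing.assert_allclose(f.values, [8.0, 16.0, 8.0])


def test_f_sphere_vertex_transitive_equal(c6):
    for sc in ("linear", "exponential"):
        f = me.f_sphere(c6, me.SphereTable(c6), LIN2.with_(sphere_coeffs=sc))
        assert np.ptp(f.log_values) == 0.0


def test_f_sphere_single_vertex():
    g = me.LabeledGraph.from_labels(["C"], [])
    f = me.f_sphere(g, me.SphereTable(g), LIN2)
    np.testing.assert_allclose(f.values, [1.0])


def test_f_sphere_vlabel_uniform_weights_reduces_to_f_sphere():
    rng = np.random.default_rng(23)
    sch = LIN2.with_(label_weight="uniform")
    for _ in range(10):
        g = random_labeled_graph(rng, int(rng.integers(2, 9)))
        sp = me.SphereTable(g)
        np.testing.assert_allclose(
            me.f_sphere_vlabel(g, sp, sch).log_values,
            me.f_sphere(g, sp, sch).log_values,
        )


def test_f_sphere_vlabel_hand_weights(coc):
    # w(C)=1, w(O)=2 realised by doubling the O entries via a custom check:
    # exponent(end) = b1*w(O)*1 + b2*w(C)*1 = 2*2 + 1 = 5
    # exponent(mid) = b1*w(C)*2 = 4
    sp = me.SphereTable(coc)
    b = LIN2.sphere_coefficients(sp.index.diameter)
    w = {"C": 1.0, "O": 2.0}
    expected = []
    for v in coc.vertices:
        expo = sum(
            b[j - 1] * w[lab] * len(sp.label_sphere(v, j, lab))
            for j in sp.sphere_sizes(v)
            for lab in ("C", "O")
        )
        expected.append(expo)
    assert expected == [5.0, 4.0, 5.0]  # the hand evaluation itself
    # the mass scheme reproduces the same shape with its own weights
    f = me.f_sphere_vlabel(coc, sp, LIN2.with_(label_weight="mass"))
    assert f.log_values[0] == f.log_values[2] != f.log_values[1]


def test_f_local_vlabel_hand_example(coc):
    ligs = me.all_local_info_graphs(coc)
    # explicit mix c_C = c_O = 0.5: end vertex sees {C,O} then {C,O,C}
    f = me.f_local_vlabel(coc, ligs, LIN2, mix={"C": 0.5, "O": 0.5})
    np.testing.assert_allclose(f.as_dict()[0], 2.5)
    # scheme-derived mix (ranked by mass: C before O -> c=(2/3, 1/3))
    f2 = me.f_local_vlabel(coc, ligs, LIN2.with_(label_mix="linear_rank"))
    np.testing.assert_allclose(f2.as_dict()[0], (2 / 3 + 1 / 3) + (2 * 2 / 3 + 1 / 3))


def test_f_local_single_label_counts_vertices(c6):
    ligs = me.all_local_info_graphs(c6)
    f = me.f_local_vlabel(c6, ligs, LIN2)
    for v in c6.vertices:
        total = sum(len(l.vertex_set) for l in ligs[v])
        np.testing.assert_allclose(f.as_dict()[v], total)


def test_complete_graph_sphere_and_local_agree():
    # with one sphere per vertex the sphere and local-info-graph functionals
    # induce the same (uniform) distribution
    k4 = me.LabeledGraph.from_labels(
        ["C", "C", "C", "C"],
        [(0, 1, "s"), (0, 2, "s"), (0, 3, "s"), (1, 2, "s"), (1, 3, "s"), (2, 3, "s")],
    )
    sp = me.SphereTable(k4)
    ligs = me.all_local_info_graphs(k4)
    p1 = me.vertex_probabilities(me.f_sphere_vlabel(k4, sp, LIN2))
    p2 = me.vertex_probabilities(me.f_local_vlabel(k4, ligs, LIN2))
    for v in k4.vertices:
        np.testing.assert_allclose(p1[v], p2[v])


def test_f_edge_hand_path():
    g = me.LabeledGraph.from_labels(["C", "C", "C"], [(0, 1, "s"), (1, 2, "d")])
    ligs = me.all_local_info_graphs(g)
    f = me.f_edge(g, ligs, LIN2)
    # b=(2,1): f(0) = 2*1 + 1*(1+2) = 5; f(1) = 2*(1+2) = 6; f(2) = 2*2 + 3 = 7
    np.testing.assert_allclose(f.values, [5.0, 6.0, 7.0])


def test_f_edge_star_from_center(star4):
    ligs = me.all_local_info_graphs(star4)
    f = me.f_edge(star4, ligs, LIN2)
    b1 = LIN2.sphere_coefficients(2)[0]
    np.testing.assert_allclose(f.as_dict()[0], b1 * 3)


def test_f_edge_unit_values_on_trees():
    # with all edge values 1, L_j(v) = j * |S_j(v)| on a tree
    import networkx as nx

    rng = np.random.default_rng(31)
    sch = LIN2.with_(edge_values={"s": 1.0, "d": 1.0})
    for _ in range(15):
        n = int(rng.integers(2, 8))
        t = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        g = me.LabeledGraph.from_labels(
            ["C"] * n, [(u, v, "s") for u, v in t.edges]
        )
        sp = me.SphereTable(g)
        ligs = me.all_local_info_graphs(g)
        b = sch.sphere_coefficients(sp.index.diameter)
        f = me.f_edge(g, ligs, sch)
        for v in g.vertices:
            expected = sum(
                b[j - 1] * j * s for j, s in sp.sphere_sizes(v).items()
            )
            np.testing.assert_allclose(f.as_dict()[v], expected)


def test_f_edge_dag_equals_enumeration():
    rng = np.random.default_rng(41)
    sch = me.CoefficientScheme(sphere_coeffs="exponential")
    for _ in range(30):
        g = random_labeled_graph(rng, int(rng.integers(2, 9)))
        ligs = me.all_local_info_graphs(g)
        rho = max(l.length for lst in ligs.values() for l in lst)
        b = sch.sphere_coefficients(rho)
        oracle = edge_functional_by_enumeration(g, sch.edge_values, b)
        f = me.f_edge(g, ligs, sch).as_dict()
        for v in g.vertices:
            np.testing.assert_allclose(f[v], oracle[v])


def test_f_combined_mixture():
    verts = (0, 1)
    fv = me.FunctionalValues.from_values(verts, [1.0, 1.0])
    fe = me.FunctionalValues.from_values(verts, [1e-300, 1.0])
    p = me.vertex_probabilities(me.f_combined(fv, fe))
    np.testing.assert_allclose([p[0], p[1]], [0.25, 0.75], atol=1e-12)
    # idempotence: identical ingredients leave the distribution unchanged
    same = me.vertex_probabilities(me.f_combined(fv, fv))
    np.testing.assert_allclose(list(same.values()), [0.5, 0.5])


def test_mixture_entropy_at_least_min():
    rng = np.random.default_rng(53)
    sch = me.CoefficientScheme()
    for _ in range(50):
        n = int(rng.integers(2, 7))
        verts = tuple(range(n))
        a = me.FunctionalValues.from_values(verts, rng.uniform(0.1, 5.0, n))
        b = me.FunctionalValues.from_values(verts, rng.uniform(0.1, 5.0, n))
        hm = me.graph_entropy(me.f_combined(a, b), sch).entropy
        ha = me.graph_entropy(a, sch).entropy
        hb = me.graph_entropy(b, sch).entropy
        assert hm >= min(ha, hb) - 1e-9


def test_isomorphism_equivariance():
    rng = np.random.default_rng(61)
    sch = me.CoefficientScheme()
    for _ in range(10):
        g = random_labeled_graph(rng, int(rng.integers(3, 9)))
        perm = {v: int(p) for v, p in zip(g.vertices, rng.permutation(g.n))}
        h = g.relabel(perm)
        fg = me.f_sphere_vlabel(g, me.SphereTable(g), sch).as_dict()
        fh = me.f_sphere_vlabel(h, me.SphereTable(h), sch).as_dict()
        for v in g.vertices:
            np.testing.assert_allclose(fg[v], fh[perm[v]])


def test_unknown_element_weight_raises(coc):
    g = me.LabeledGraph.from_labels(["C", "Zz"], [(0, 1, "s")])
    with pytest.raises(KeyError):
        me.f_sphere_vlabel(g, me.SphereTable(g), me.CoefficientScheme())


def test_positive_values_required():
    with pytest.raises(ValueError):
        me.FunctionalValues.from_values((0, 1), [1.0, 0.0])
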