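"""Superindex construction and the supervised evaluation harness."""

import numpy as np
import pandas as pd
import pytest

import molentropy as me


def _toy_table(n=60, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    cols = {}
    if informative:
        cols["signal"] = y * 2.0 + rng.normal(0, 0.05, n)
    for i in range(4):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    frame = pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n)], name="graph"))
    groups = {c: ("labeled" if c == "signal" else "unlabeled") for c in frame.columns}
    return me.DescriptorTable(frame, pd.Series(y, index=frame.index), groups)


def test_build_superindex_shape_and_groups():
    graphs = [me.make_random_molecule(8, seed=s) for s in range(3)]
    table = me.build_superindex(graphs, labels=[0, 1, 0])
    assert table.frame.shape == (3, 16)
    assert len(table.features_in_group("unlabeled")) == 11
    assert len(table.features_in_group("labeled")) == 5
    small = me.build_superindex(graphs[:1], feature_set=["W", "I_D", "I_orb"])
    assert small.frame.shape == (1, 3)
    with pytest.raises(KeyError):
        me.build_superindex(graphs, feature_set=["no_such_index"])


def test_superindex_row_order_follows_input_order():
    graphs = [me.make_random_molecule(7, seed=s, name=f"m{s}") for s in range(4)]
    t1 = me.build_superindex(graphs, feature_set=["W", "I_D"])
    t2 = me.build_superindex(graphs[::-1], feature_set=["W", "I_D"])
    pd.testing.assert_frame_equal(t1.frame, t2.frame.iloc[::-1])


@pytest.mark.parametrize(
    "prec, sens, expected",
    [(67.9, 80.1, 73.5), (68.7, 68.3, 68.5), (66.5, 70.7, 68.5)],
)
def test_f_measure_harmonic_mean(prec, sens, expected):
    assert round(me.f_measure(prec, sens), 1) == expected


def test_f_measure_fixed_point():
    assert me.f_measure(64.0, 64.0) == pytest.approx(64.0)


def test_metrics_from_confusion():
    r = me.metrics_from_confusion(tp=40, fp=10, tn=35, fn=15)
    assert r.accuracy == pytest.approx(75.0)
    assert r.sensitivity == pytest.approx(40 / 55 * 100)
    assert r.specificity == pytest.approx(35 / 45 * 100)
    assert r.precision == pytest.approx(80.0)
    assert r.f_measure == pytest.approx(
        2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
    )
    with pytest.raises(ValueError):
        me.metrics_from_confusion(0, 0, 0, 0)


def test_accuracy_from_rates_identity():
    r = me.metrics_from_confusion(tp=40, fp=10, tn=35, fn=15)
    acc = me.accuracy_from_rates(r.sensitivity, r.specificity, 55, 45)
    assert acc == pytest.approx(r.accuracy)


@pytest.mark.parametrize("model", ["rf", "svm"])
def test_crossvalidate_separable_table(model):
    table = _toy_table(seed=1)
    r = me.crossvalidate(table, model=model, folds=5, seed=0)
    assert r.accuracy > 95.0
    assert r.f_measure > 95.0


def test_crossvalidate_deterministic():
    table = _toy_table(seed=2)
    a = me.crossvalidate(table, model="rf", folds=5, seed=3)
    b = me.crossvalidate(table, model="rf", folds=5, seed=3)
    assert a.confusion == b.confusion and a.accuracy == b.accuracy


def test_crossvalidate_pooled_confusion_consistency():
    table = _toy_table(seed=4, informative=False)
    r = me.crossvalidate(table, model="rf", folds=5, seed=0)
    tp, fp, tn, fn = r.confusion
    again = me.metrics_from_confusion(tp, fp, tn, fn)
    assert r.accuracy == pytest.approx(again.accuracy, abs=1e-9)
    assert r.f_measure == pytest.approx(again.f_measure, abs=1e-9)


def test_crossvalidate_guards():
    table = _toy_table(n=10)
    with pytest.raises(ValueError):
        me.crossvalidate(table, folds=10)  # fewer than `folds` rows per class


def test_greedy_selection_finds_signal_first():
    table = _toy_table(n=80, seed=5)
    chosen = me.greedy_feature_selection(table)
    assert chosen[0] == "signal"


def test_greedy_selection_duplicate_and_full_size():
    table = _toy_table(n=40, seed=6)
    dup = table.frame.copy()
    dup["signal_copy"] = dup["signal"]
    t2 = me.DescriptorTable(dup, table.labels, dict(table.groups, signal_copy="labeled"))
    m = len(t2.feature_names)
    full = me.greedy_feature_selection(t2, target_size=m)
    assert sorted(full) == sorted(t2.feature_names)
    assert len(set(full)) == m  # nothing selected twice


def test_subset_experiment_shapes_and_sigma():
    rng = np.random.default_rng(7)
    n = 60
    y = np.array([0, 1] * (n // 2))
    cols = {f"u{i}": rng.normal(size=n) for i in range(7)}
    cols.update({f"l{i}": y + rng.normal(0, 0.3, n) for i in range(2)})
    frame = pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n)], name="graph"))
    groups = {c: ("unlabeled" if c.startswith("u") else "labeled") for c in frame}
    table = me.DescriptorTable(frame, pd.Series(y, index=frame.index), groups)

    res = me.subset_experiment(table, model="rf", n_subsets=3, folds=5, seed=0)
    for regime in ("unlabeled_only", "mixed"):
        assert len(res[regime]["reports"]) == 3
        mean, sigma = res[regime]["accuracy"]
        assert 0.0 <= mean <= 100.0 and sigma >= 0.0
    # feature pool exactly subset-sized -> all unlabeled subsets coincide -> sigma 0
    assert all(len(s) == 7 for s in res["unlabeled_only"]["subsets"])
    assert res["unlabeled_only"]["accuracy"][1] == pytest.approx(0.0)
    # labeled signal only: mixed regime beats unlabeled-only on average
    assert res["mixed"]["accuracy"][0] > res["unlabeled_only"]["accuracy"][0]


def test_subset_experiment_single_subset_matches_crossvalidate():
    table = _toy_table(n=60, seed=8)
    dup = table.frame.copy()
    for i in range(4, 7):  # pad the unlabeled pool to seven features
        dup[f"noise{i}"] = dup[f"noise{i - 4}"] * 0.5 + 1.0
    groups = {c: ("labeled" if c == "signal" else "unlabeled") for c in dup}
    groups["signal2"] = "labeled"
    dup["signal2"] = dup["signal"] * -1.0
    t = me.DescriptorTable(dup, table.labels, groups)
    res = me.subset_experiment(t, model="rf", n_subsets=1, folds=5, seed=9)
    feats = res["mixed"]["subsets"][0]
    direct = me.crossvalidate(t, model="rf", folds=5, seed=9, features=feats)
    assert res["mixed"]["reports"][0].confusion == direct.confusion
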