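"""The ten classifiers against independent loop-based oracles."""

import math

import numpy as np
import pytest

from beenose import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    classify,
    classify_1nn,
    classify_811,
    classify_nb,
    distance,
    parse_classifier,
)
from conftest import random_table

METRICS = ("canberra", "euclidean", "manhattan", "maxmin")


# ---------------------------------------------------------------------------
# Independent scalar oracles (plain loops, no numpy vectorization)
# ---------------------------------------------------------------------------

def oracle_distance(metric, x, y, lo=None, hi=None):
    if metric == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if metric == "manhattan":
        return sum(abs(a - b) for a, b in zip(x, y))
    if metric == "canberra":
        total = 0.0
        for a, b in zip(x, y):
            den = abs(a) + abs(b)
            if den > 0:
                total += abs(a - b) / den
        return total
    if metric == "maxmin":
        total = 0.0
        for a, b, l, h in zip(x, y, lo, hi):
            if h > l:
                an, bn = (a - l) / (h - l), (b - l) / (h - l)
            else:
                an = bn = 0.0
            total += (an - bn) ** 2
        return math.sqrt(total)
    raise ValueError(metric)


def _tie_key(label):
    return (0, int(label), "") if not isinstance(label, str) else (1, 0, label)


def oracle_1nn(table, x, metric):
    best_d, best_labels = None, []
    for row in table.rows:
        d = oracle_distance(metric, row.descriptors, x, table.attr_min, table.attr_max)
        if best_d is None or d < best_d:
            best_d, best_labels = d, [row.class_label]
        elif d == best_d:
            best_labels.append(row.class_label)
    return min(best_labels, key=_tie_key)


def oracle_811(table, x, metric, delta):
    votes = {}
    for row in table.rows:
        d = oracle_distance(metric, row.descriptors, x, table.attr_min, table.attr_max)
        votes[row.class_label] = votes.get(row.class_label, 0.0) + 1.0 / (d + delta)
    best = max(votes.values())
    return min([c for c, v in votes.items() if v == best], key=_tie_key)


def oracle_nb(table, x, eps, variant):
    classes = sorted(set(r.class_label for r in table.rows), key=_tie_key)
    scores = {}
    for c in classes:
        rows = [r for r in table.rows if r.class_label == c]
        s = 0.0
        for i in range(6):
            window = eps * (table.attr_max[i] - table.attr_min[i])
            hits = sum(1 for r in rows if abs(r.descriptors[i] - x[i]) <= window)
            s += hits / len(rows)
        if variant == "nb2":
            s *= len(rows) / len(table.rows)
        scores[c] = s
    best = max(scores.values())
    return min([c for c, v in scores.items() if v == best], key=_tie_key)


# ---------------------------------------------------------------------------
# Names and specs
# ---------------------------------------------------------------------------

def test_m_numbers_map_to_study_names():
    assert [parse_classifier(f"m{i}").name for i in range(1, 11)] == list(CLASSIFIER_NAMES)


@pytest.mark.parametrize("name,family,metric", [
    ("canberra.1nn", "1nn", "canberra"),
    ("maxminnormalized.811", "811", "maxmin"),
    ("eps = 0.01.nb", "nb", "euclidean"),
    ("eps=0.05.nb2", "nb2", "euclidean"),
])
def test_parse_classifier_names(name, family, metric):
    spec = parse_classifier(name)
    assert spec.family == family
    assert spec.metric == metric
    if family == "nb2" and "0.05" in name:
        assert spec.eps == 0.05


def test_unknown_classifier_lists_valid_names():
    with pytest.raises(ValueError, match="canberra.1nn"):
        parse_classifier("svm")


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec(family="knn")
    with pytest.raises(ValueError):
        ClassifierSpec(family="nb", eps=0.0)
    with pytest.raises(ValueError):
        ClassifierSpec(family="811", delta=0.0)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("metric", METRICS)
def test_distance_identity(metric):
    x = np.array([1.0, -2.0, 0.0, 3.5, 4.0, -1.0])
    assert distance(metric, x, x, np.full(6, -5.0), np.full(6, 5.0)) == 0.0


def test_canberra_hand_value():
    assert distance("canberra", (1.0, 3.0), (3.0, 1.0)) == pytest.approx(1.0)


def test_canberra_zero_zero_convention():
    # both coordinates zero: the 0/0 term contributes 0
    assert distance("canberra", (0.0, 1.0), (0.0, 3.0)) == pytest.approx(0.5)
    assert distance("canberra", (0.0,), (0.0,)) == 0.0


def test_unit_offset_distances():
    z, o = np.zeros(6), np.ones(6)
    assert distance("manhattan", z, o) == pytest.approx(6.0)
    assert distance("euclidean", z, o) == pytest.approx(math.sqrt(6.0))


def test_maxmin_constant_attribute_maps_to_zero():
    lo = np.array([0.0, 2.0])
    hi = np.array([10.0, 2.0])  # second attribute constant
    d = distance("maxmin", (0.0, -7.0), (5.0, 99.0), lo, hi)
    assert d == pytest.approx(0.5)


def test_maxmin_no_clipping_outside_training_range():
    lo, hi = np.zeros(1), np.ones(1)
    assert distance("maxmin", (2.0,), (0.0,), lo, hi) == pytest.approx(2.0)


@pytest.mark.parametrize("metric", METRICS)
def test_distance_matches_oracle(metric):
    rng = np.random.default_rng(7)
    lo, hi = np.full(6, -4.0), np.full(6, 4.0)
    for _ in range(50):
        x, y = rng.uniform(-4, 4, 6), rng.uniform(-4, 4, 6)
        assert distance(metric, x, y, lo, hi) == pytest.approx(
            oracle_distance(metric, x, y, lo, hi), rel=1e-12)


# ---------------------------------------------------------------------------
# 1-NN
# ---------------------------------------------------------------------------

def test_1nn_single_row_forced():
    rng = np.random.default_rng(0)
    t = random_table(rng, n_rows=1)
    assert classify_1nn(t, rng.normal(size=6)) == t.rows[0].class_label


def test_1nn_exact_match():
    rng = np.random.default_rng(1)
    t = random_table(rng, n_rows=8)
    for row in t.rows:
        assert classify_1nn(t, row.descriptors.copy(), "manhattan") == row.class_label


@pytest.mark.parametrize("metric", METRICS)
def test_1nn_matches_bruteforce_oracle(metric):
    rng = np.random.default_rng(42)
    for trial in range(10):
        t = random_table(rng, n_rows=int(rng.integers(4, 16)))
        for _ in range(10):
            x = rng.normal(0.0, 3.0, 6)
            assert classify_1nn(t, x, metric) == oracle_1nn(t, x, metric)


def test_1nn_permutation_invariant():
    rng = np.random.default_rng(3)
    t = random_table(rng, n_rows=10)
    from beenose import DecisionTable

    perm = rng.permutation(len(t.rows))
    t2 = DecisionTable(rows=[t.rows[i] for i in perm])
    for _ in range(20):
        x = rng.normal(0.0, 3.0, 6)
        for metric in METRICS:
            assert classify_1nn(t, x, metric) == classify_1nn(t2, x, metric)


def test_1nn_agrees_with_sklearn():
    """Off-the-shelf euclidean 1-NN agrees on >= 99% of random queries
    (disagreements possible only at exact distance ties)."""
    from sklearn.neighbors import KNeighborsClassifier

    rng = np.random.default_rng(99)
    t = random_table(rng, n_rows=30)
    knn = KNeighborsClassifier(n_neighbors=1).fit(t.X, t.labels)
    queries = rng.normal(0.0, 3.0, (200, 6))
    ours = [classify_1nn(t, q, "euclidean") for q in queries]
    theirs = knn.predict(queries)
    agree = sum(a == b for a, b in zip(ours, theirs)) / len(queries)
    assert agree >= 0.99


# ---------------------------------------------------------------------------
# 811 weighted voting
# ---------------------------------------------------------------------------

def test_811_unanimous_class():
    rng = np.random.default_rng(5)
    t = random_table(rng, n_rows=6, classes=(5,))
    assert classify_811(t, rng.normal(size=6)) == 5


def test_811_coincident_row_dominates():
    rng = np.random.default_rng(6)
    t = random_table(rng, n_rows=12)
    for row in t.rows:
        assert classify_811(t, row.descriptors.copy(), "euclidean", delta=1e-10) == row.class_label


def test_811_hand_computed_votes():
    from beenose import DecisionTable, FeatureVector

    rows = [
        FeatureVector(np.array([0.0] * 6), 5, "a", "M1", "wooden"),
        FeatureVector(np.array([1.0] * 6), 5, "b", "M1", "wooden"),
        FeatureVector(np.array([2.0] * 6), 7, "c", "M1", "wooden"),
        FeatureVector(np.array([3.0] * 6), 7, "d", "M1", "wooden"),
    ]
    t = DecisionTable(rows=rows)
    x = np.array([1.4] * 6)
    delta = 1e-6
    votes = {5: 0.0, 7: 0.0}
    for row in rows:
        d = oracle_distance("manhattan", row.descriptors, x)
        votes[row.class_label] += 1.0 / (d + delta)
    expected = max(votes, key=votes.get)
    assert classify_811(t, x, "manhattan", delta) == expected


@pytest.mark.parametrize("metric", METRICS)
def test_811_matches_bruteforce_oracle(metric):
    rng = np.random.default_rng(44)
    for _ in range(10):
        t = random_table(rng, n_rows=12)
        for _ in range(10):
            x = rng.normal(0.0, 3.0, 6)
            assert classify_811(t, x, metric, 1e-10) == oracle_811(t, x, metric, 1e-10)


def test_811_approaches_1nn_as_delta_vanishes():
    rng = np.random.default_rng(8)
    t = random_table(rng, n_rows=10)
    for row in t.rows:
        x = row.descriptors.copy()
        assert classify_811(t, x, "euclidean", delta=1e-12) == classify_1nn(t, x, "euclidean")


# ---------------------------------------------------------------------------
# Epsilon-indiscernibility Naive Bayes
# ---------------------------------------------------------------------------

def test_nb_saturated_ratios():
    """Query inside every window of class 7 and outside all others -> score 6."""
    from beenose import DecisionTable, FeatureVector

    rows = [FeatureVector(np.full(6, 0.0) + i * 0.001, 7, f"p{i}", "M1", "wooden")
            for i in range(3)]
    rows += [FeatureVector(np.full(6, 100.0) + i, 5, f"n{i}", "M1", "wooden") for i in range(3)]
    t = DecisionTable(rows=rows)
    x = np.full(6, 0.0005)
    assert classify_nb(t, x, eps=0.01, variant="nb") == 7
    assert oracle_nb(t, x, 0.01, "nb") == 7
    # saturated: every class-7 row within the window on all six attributes
    window = 0.01 * (t.attr_max - t.attr_min)
    assert np.all(np.abs(np.vstack([r.descriptors for r in rows[:3]]) - x) <= window)


def test_nb_constant_attribute_exact_equality():
    from beenose import DecisionTable, FeatureVector

    rows = [FeatureVector(np.zeros(6), 5, "a", "M1", "wooden"),
            FeatureVector(np.zeros(6), 6, "b", "M1", "wooden")]
    t = DecisionTable(rows=rows)
    # all attributes constant: window = 0, only exact equality hits
    assert classify_nb(t, np.zeros(6), eps=0.5, variant="nb") == 5  # tie -> lowest label
    assert classify_nb(t, np.full(6, 1e-9), eps=0.5, variant="nb") == 5


@pytest.mark.parametrize("variant", ["nb", "nb2"])
def test_nb_matches_loop_oracle(variant):
    rng = np.random.default_rng(45)
    for _ in range(10):
        t = random_table(rng, n_rows=12)
        for _ in range(10):
            x = rng.normal(0.0, 3.0, 6)
            for eps in (0.01, 0.1, 0.5):
                assert classify_nb(t, x, eps, variant) == oracle_nb(t, x, eps, variant)


def test_nb_variants_can_differ():
    """The class prior reweights nb2 away from nb on unbalanced tables."""
    rng = np.random.default_rng(46)
    diffs = 0
    for _ in range(30):
        t = random_table(rng, n_rows=14, classes=(5, 5, 5, 7))
        x = rng.normal(0.0, 3.0, 6)
        if classify_nb(t, x, 0.3, "nb") != classify_nb(t, x, 0.3, "nb2"):
            diffs += 1
    assert diffs > 0


def test_dispatch_covers_all_ten(table_m1_wooden):
    x = table_m1_wooden.rows[0]
    for name in CLASSIFIER_NAMES:
        label = classify(table_m1_wooden, x, parse_classifier(name))
        assert label in table_m1_wooden.class_set
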