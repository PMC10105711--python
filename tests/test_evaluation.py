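import itertools
from fractions import Fraction

import numpy as np
import pytest

from syndeep.evaluation import (ConfusionCounts, McNemarResult, MetricsReport,
                                compute_metrics, confusion_from_predictions,
                                cross_validate, mcnemar, roc_auc,
                                stratified_kfold)
from syndeep.models import ModelSpec


# --------------------------------------------------------------- fold layout

def test_hundred_balanced_records_make_ten_even_folds():
    y = np.array([0, 1] * 50)
    folds = stratified_kfold(y, k=10, seed=0)
    for f in range(10):
        mask = folds == f
        assert mask.sum() == 10
        assert y[mask].sum() == 5


def test_k_equal_n_is_leave_one_out():
    y = np.array([0, 1] * 5)
    with pytest.raises(ValueError):
        stratified_kfold(y, k=10, seed=0)  # k exceeds per-class count
    folds = stratified_kfold(y, k=5, seed=0)
    assert sorted(np.bincount(folds)) == [2] * 5


def test_fold_assignment_partitions_and_is_seeded():
    y = np.array([0, 1] * 30)
    a = stratified_kfold(y, k=10, seed=4)
    b = stratified_kfold(y, k=10, seed=4)
    c = stratified_kfold(y, k=10, seed=5)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
    assert set(a) == set(range(10))


def test_k_larger_than_n_errors():
    with pytest.raises(ValueError, match="exceeds"):
        stratified_kfold(np.array([0, 1]), k=3, seed=0)


# ------------------------------------------------------------ metric formulas

def _metrics_oracle(tp, fp, tn, fn):
    """Exact-rational brute-force evaluation of the printed formulas."""
    tp, fp, tn, fn = map(Fraction, (tp, fp, tn, fn))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else Fraction(0)
    spe = tn / (tn + fp) if tn + fp else Fraction(0)
    pre = tp / (tp + fp) if tp + fp else Fraction(0)
    f = 2 * sen * pre / (sen + pre) if sen + pre else Fraction(0)
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = float(tp * tn - fp * fn) / float(mcc_den2) ** 0.5 if mcc_den2 else 0.0
    pc = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (acc - pc) / (1 - pc) if pc != 1 else Fraction(0)
    return dict(accuracy=acc, sensitivity=sen, specificity=spe, precision=pre,
                f_score=f, mcc=mcc, kappa=kappa)


def test_perfect_classifier_metrics_all_one():
    r = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
    for name in ("accuracy", "sensitivity", "specificity", "precision",
                 "f_score", "mcc", "kappa"):
        assert getattr(r, name) == 1.0


def test_total_disagreement_metrics():
    r = compute_metrics(ConfusionCounts(tp=0, fp=50, tn=0, fn=50))
    assert r.accuracy == 0.0
    assert r.mcc == -1.0
    assert r.kappa == -1.0


def test_hand_evaluated_confusion_table():
    r = compute_metrics(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
    assert r.accuracy == pytest.approx(0.85)
    assert r.sensitivity == pytest.approx(0.90)
    assert r.specificity == pytest.approx(0.80)
    assert r.precision == pytest.approx(0.8182, abs=1e-4)
    assert r.f_score == pytest.approx(0.8571, abs=1e-4)
    assert r.mcc == pytest.approx(0.7035, abs=1e-4)
    assert r.kappa == pytest.approx(0.70, abs=1e-4)


def test_metrics_match_rational_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        tp, fp, tn, fn = rng.integers(0, 200, size=4)
        if tp + fp + tn + fn == 0:
            continue
        ours = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        oracle = _metrics_oracle(int(tp), int(fp), int(tn), int(fn))
        for name, expected in oracle.items():
            assert getattr(ours, name) == pytest.approx(float(expected), abs=1e-12), name


def test_balanced_truth_accuracy_identity():
    """accuracy = (sensitivity + specificity) / 2 whenever TP+FN = TN+FP."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        pos = int(rng.integers(1, 100))
        tp = int(rng.integers(0, pos + 1))
        fp = int(rng.integers(0, pos + 1))
        c = ConfusionCounts(tp=tp, fp=fp, tn=pos - fp, fn=pos - tp)
        r = compute_metrics(c)
        assert r.accuracy == pytest.approx((r.sensitivity + r.specificity) / 2)


def test_empty_table_errors():
    with pytest.raises(ValueError):
        compute_metrics(ConfusionCounts(0, 0, 0, 0))


# ----------------------------------------------------------------------- AUC

def _auc_brute_force(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def test_auc_perfect_ranking():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auc_all_ties_is_half():
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5


def test_auc_worked_example():
    assert roc_auc([0.2, 0.4, 0.1, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)


def test_auc_matches_brute_force_on_random_scores():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 2)  # coarse grid induces ties
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_brute_force(scores, labels))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    scores = rng.random(50)
    labels = rng.integers(0, 2, size=50)
    base = roc_auc(scores, labels)
    assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(base)
    assert roc_auc(scores**3 + 7, labels) == pytest.approx(base)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


# ------------------------------------------------------------------- McNemar

def _mcnemar_counts(b, c):
    """Construct paired prediction vectors with exactly B and C discordances."""
    y = np.zeros(b + c + 4, dtype=int)
    a_pred = y.copy()
    b_pred = y.copy()
    b_pred[:b] = 1          # a right, b wrong
    a_pred[b:b + c] = 1     # a wrong, b right
    return a_pred, b_pred, y


def test_mcnemar_one_sided_discordance():
    a, b, y = _mcnemar_counts(25, 0)
    res = mcnemar(a, b, y)
    assert (res.b, res.c) == (25, 0)
    assert res.statistic == pytest.approx(23.04)


def test_mcnemar_equal_discordance():
    a, b, y = _mcnemar_counts(10, 10)
    res = mcnemar(a, b, y)
    assert res.statistic == pytest.approx(0.05)
    assert res.p_value > 0.5


def test_mcnemar_no_discordance_not_applicable():
    y = np.array([0, 1, 0, 1])
    pred = np.array([0, 1, 1, 0])
    res = mcnemar(pred, pred, y)
    assert not res.applicable
    assert (res.b, res.c) == (0, 0)


def test_mcnemar_symmetric_in_b_and_c():
    rng = np.random.default_rng(9)
    for _ in range(100):
        b, c = map(int, rng.integers(0, 60, size=2))
        if b + c == 0:
            continue
        pa, pb, y = _mcnemar_counts(b, c)
        fwd = mcnemar(pa, pb, y)
        rev = mcnemar(pb, pa, y)
        assert fwd.statistic == pytest.approx(rev.statistic)
        assert (fwd.b, fwd.c) == (rev.c, rev.b)
        assert fwd.statistic == pytest.approx((abs(b - c) - 1) ** 2 / (b + c))


# ---------------------------------------------------------- cross-validation

def test_cross_validate_planted_signal(planted_balanced):
    universe, schema, signal, balanced = planted_balanced
    spec = ModelSpec("syndeep_mlp", {"epochs": 20}, seed=0)
    cv = cross_validate(spec, balanced[:600], universe, 6, k=5, seed=0,
                        schema=schema)
    assert cv.mean.accuracy > 0.9
    assert len(cv.per_fold) == 5
    # union of test folds covers every record exactly once
    assert cv.fold_assignment.shape == (600,)
    assert np.all(np.bincount(cv.fold_assignment) == 120)


def test_cross_validate_null_is_chance_level(planted_balanced):
    universe, schema, signal, balanced = planted_balanced
    rng = np.random.default_rng(123)
    y_perm = rng.permutation([r.label for r in balanced[:600]])
    import dataclasses
    shuffled = [dataclasses.replace(r, label=int(l))
                for r, l in zip(balanced[:600], y_perm)]
    spec = ModelSpec("knn", seed=0)
    cv = cross_validate(spec, shuffled, universe, 6, k=5, seed=0, schema=schema)
    assert 0.4 < cv.mean.accuracy < 0.6


def test_fold_isolation_via_canary_feature(planted_balanced):
    """A canary column equal to the label makes held-out AUC ~1 only because
    the canary is in X; removing it drops AUC to the signal level, showing
    scaling/fitting never see test rows."""
    from syndeep.evaluation import _cross_validate_xy

    rng = np.random.default_rng(5)
    n = 400
    X = rng.normal(size=(n, 10))
    y = rng.integers(0, 2, size=n)
    spec = ModelSpec("rf", seed=0)
    with_canary = _cross_validate_xy(spec, np.column_stack([X, y]), y, k=5, seed=0)
    without = _cross_validate_xy(spec, X, y, k=5, seed=0)
    assert with_canary.mean.auc > 0.99
    assert 0.4 < without.mean.auc < 0.6
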