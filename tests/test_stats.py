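"""Class comparisons, grouped cross-validation, balancing, CART."""

import math

import numpy as np
import pandas as pd
import pytest

from promisite.stats import (ConfusionCounts, GroupedDataset, balance_classes,
                             cart_train_eval, class_comparison,
                             comparison_table, cv_split, performance_metrics)


# ---------------------------------------------------------------------------
# metrics

def test_metric_formulas():
    m = performance_metrics(ConfusionCounts(TP=75, TN=67, FP=33, FN=25))
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(0.67)
    assert m["accuracy"] == pytest.approx((75 + 67) / 200)
    # the printed "accuracy" formula TP/(TP+FP) is precision
    m2 = performance_metrics(ConfusionCounts(TP=68, TN=0, FP=32, FN=0))
    assert m2["precision_eq5"] == pytest.approx(0.68)


def test_metric_zero_denominator_undefined():
    m = performance_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
    assert math.isnan(m["sensitivity"]) and math.isnan(m["precision_eq5"])


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


def test_sensitivity_plus_fn_rate_is_one():
    c = ConfusionCounts(TP=40, TN=10, FP=5, FN=20)
    m = performance_metrics(c)
    assert m["sensitivity"] + c.FN / (c.TP + c.FN) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# comparisons

def _dataset(shift=0.0, n=50, seed=0, n_desc=1):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, delta in (("S", 0.0), ("MP", shift / 2), ("HP", shift)):
        for _ in range(n):
            rows.append(rng.normal(delta, 1.0, n_desc))
            labels.append(cls)
    return pd.DataFrame(rows, columns=[f"d{i}" for i in range(n_desc)]), labels


def test_identical_classes_skipped_with_reason():
    rep = class_comparison([1.0] * 9, ["S"] * 3 + ["MP"] * 3 + ["HP"] * 3)
    assert rep.skipped == "zero within-class variance for all classes"
    assert math.isnan(rep.p_value)


def test_planted_shift_detected():
    # HP mean = S mean + 3 sd -> overwhelming ANOVA signal at n = 50/class
    detected = 0
    for seed in range(20):
        X, labels = _dataset(shift=3.0, n=50, seed=seed)
        rep = class_comparison(X["d0"], labels, n_comparisons=72)
        if rep.p_value < 1e-3:
            detected += 1
    assert detected == 20


def test_bonferroni_multiplies_and_caps():
    X, labels = _dataset(shift=0.0, n=20, seed=1)
    rep = class_comparison(X["d0"], labels, n_comparisons=72)
    for pair in rep.pairwise.values():
        assert pair["p_bonferroni"] == pytest.approx(
            min(1.0, pair["p_raw"] * 72))


def test_comparison_table_shape():
    X, labels = _dataset(shift=1.0, n=10, seed=2, n_desc=5)
    tab = comparison_table(X, labels)
    assert len(tab) == 5
    assert {"descriptor", "F", "p", "min_p_bonferroni"} <= set(tab.columns)


def test_chi2_categorical_path():
    values = ["a"] * 18 + ["b"] * 2 + ["a"] * 3 + ["b"] * 17
    labels = ["S"] * 20 + ["HP"] * 20
    rep = class_comparison(values, labels, categorical=True)
    assert rep.kind == "chi2"
    assert rep.p_value < 1e-4


# ---------------------------------------------------------------------------
# folds and balancing

def _grouped(n_groups=10, rows_per_group=3, seed=0, two_class=True):
    rng = np.random.default_rng(seed)
    rows, y, g = [], [], []
    for i in range(n_groups):
        cls = "HP" if (i % 2 == 0 or not two_class) else "S"
        for _ in range(rows_per_group):
            rows.append(rng.normal(size=2))
            y.append(cls)
            g.append(f"g{i:02d}")
    return GroupedDataset(pd.DataFrame(rows, columns=["a", "b"]),
                          np.array(y), np.array(g))


def test_cv_split_balanced_and_group_disjoint():
    ds = _grouped(n_groups=10)
    folds = cv_split(ds, n_folds=5, seed=3)
    for train, test in folds:
        assert set(ds.groups[train]) & set(ds.groups[test]) == set()
    sizes = [len({g for g in ds.groups[test]}) for _, test in folds]
    assert sizes == [2] * 5


def test_cv_split_deterministic_and_rejects_few_groups():
    ds = _grouped(n_groups=7)
    f1 = cv_split(ds, n_folds=5, seed=9)
    f2 = cv_split(ds, n_folds=5, seed=9)
    for (a, b), (c, d) in zip(f1, f2):
        assert np.array_equal(a, c) and np.array_equal(b, d)
    with pytest.raises(ValueError):
        cv_split(_grouped(n_groups=4), n_folds=5)


def test_balance_undersamples_majority_groups():
    rng = np.random.default_rng(5)
    rows, y, g = [], [], []
    for i in range(100):
        rows.append(rng.normal(size=1)); y.append("HP"); g.append(f"hp{i}")
    for i in range(20):
        rows.append(rng.normal(size=1)); y.append("S"); g.append(f"s{i}")
    ds = GroupedDataset(pd.DataFrame(rows, columns=["x"]), np.array(y), np.array(g))
    bal = balance_classes(ds, seed=0)
    hp_groups = {gr for gr, c in zip(bal.groups, bal.y) if c == "HP"}
    s_groups = {gr for gr, c in zip(bal.groups, bal.y) if c == "S"}
    assert len(hp_groups) == len(s_groups) == 20
    assert hp_groups <= {f"hp{i}" for i in range(100)}  # subset of originals


def test_balance_already_balanced_unchanged():
    ds = _grouped(n_groups=10)
    bal = balance_classes(ds, seed=1)
    assert sorted(bal.groups) == sorted(ds.groups)


# ---------------------------------------------------------------------------
# CART

def _separable_dataset(n_groups=20, seed=0):
    rng = np.random.default_rng(seed)
    rows, y, g = [], [], []
    for i in range(n_groups):
        cls = "HP" if i % 2 == 0 else "S"
        vol = rng.uniform(600, 900) if cls == "HP" else rng.uniform(100, 400)
        for _ in range(4):
            rows.append([vol + rng.normal(0, 10), rng.normal()])
            y.append(cls); g.append(f"g{i:02d}")
    return GroupedDataset(pd.DataFrame(rows, columns=["volume", "noise"]),
                          np.array(y), np.array(g))


def test_cart_perfect_on_separable_planted_data():
    rep = cart_train_eval(_separable_dataset(), repeats=5, seed=0,
                          positive_label="HP")
    assert rep.metrics_mean["sensitivity"] == 1.0
    assert rep.metrics_mean["specificity"] == 1.0


def test_cart_root_split_uses_strongest_feature():
    # volume carries the whole impurity decrease in this construction
    rep = cart_train_eval(_separable_dataset(), repeats=2, seed=1,
                          positive_label="HP")
    assert rep.tree_json["split"]["feature"] == "volume"
    assert rep.tree_json["node_pct"] == 100.0


def test_cart_permuted_labels_near_chance():
    rng = np.random.default_rng(7)
    ds = _separable_dataset(n_groups=30, seed=2)
    # permute labels at group level to break the signal but keep grouping
    groups = sorted(set(ds.groups))
    perm = dict(zip(groups, rng.permutation([("HP" if i % 2 == 0 else "S")
                                             for i in range(len(groups))])))
    y_perm = np.array([perm[g] for g in ds.groups])
    ds_perm = GroupedDataset(ds.X, y_perm, ds.groups)
    rep = cart_train_eval(ds_perm, repeats=30, seed=3, positive_label="HP")
    assert abs(rep.metrics_mean["accuracy"] - 0.5) <= 0.1


def test_cart_drops_constant_features():
    ds = _separable_dataset()
    ds.X["const"] = 1.0
    rep = cart_train_eval(ds, repeats=2, seed=0)
    assert rep.dropped_features == ["const"]
    assert "const" not in rep.feature_names
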