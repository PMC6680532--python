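"""Descriptor statistics across promiscuity classes and CART discrimination.

Class comparisons use one-way ANOVA, pairwise Student t-tests with a
Bonferroni correction over the descriptor family, and chi-squared tests
for categorical descriptors.  Selective-vs-highly-promiscuous
discrimination uses a balanced binary CART evaluated with group-aware
five-fold cross-validation: all rows of one group (one Pocket-Cluster,
or one Ligand-Cluster for ligand rows) land in the same fold, so
held-out performance is not inflated by near-duplicate rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.tree import DecisionTreeClassifier, export_text

__all__ = [
    "ConfusionCounts",
    "GroupedDataset",
    "ComparisonReport",
    "class_comparison",
    "comparison_table",
    "cv_split",
    "balance_classes",
    "cart_train_eval",
    "performance_metrics",
    "CartReport",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def performance_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), standard accuracy
    (TP+TN)/total, and ``precision_eq5`` = TP/(TP+FP).

    ``precision_eq5`` reproduces a published "accuracy" formula verbatim;
    as written it is the positive predictive value (precision), so the
    standard accuracy is reported alongside.  Zero denominators yield NaN
    (metric undefined).
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
        "accuracy": ratio(c.TP + c.TN, c.total),
        "precision_eq5": ratio(c.TP, c.TP + c.FP),
    }


@dataclass
class GroupedDataset:
    """Descriptor rows with a promiscuity label and a group per row.

    Groups (Pocket-Cluster ids for pocket rows, Ligand-Cluster ids for
    ligand rows) are the unit of cross-validation assignment and of
    class balancing.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")

    def subset(self, idx: np.ndarray) -> "GroupedDataset":
        return GroupedDataset(self.X.iloc[idx].reset_index(drop=True),
                              self.y[idx], self.groups[idx])

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# class comparisons

@dataclass
class ComparisonReport:
    descriptor: str
    kind: str                               # "anova" or "chi2"
    statistic: float = float("nan")
    p_value: float = float("nan")
    pairwise: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    class_stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    skipped: str | None = None


def class_comparison(values: Sequence[float], labels: Sequence[str],
                     descriptor: str = "", categorical: bool = False,
                     n_comparisons: int = 1) -> ComparisonReport:
    """Compare one descriptor across promiscuity classes.

    Continuous descriptors: one-way ANOVA across all classes plus
    pairwise two-sample t-tests whose p-values are Bonferroni-multiplied
    by ``n_comparisons`` (the size of the descriptor family tested).
    Categorical descriptors: chi-squared on the class-by-level
    contingency table.  Degenerate inputs (all values identical, a class
    with < 2 rows) are skipped with a reason rather than producing
    spurious p-values.
    """
    values = np.asarray(values, dtype=float if not categorical else object)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    rep = ComparisonReport(descriptor=descriptor,
                           kind="chi2" if categorical else "anova")
    if len(classes) < 2:
        rep.skipped = "fewer than two classes"
        return rep
    groups = [values[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        rep.skipped = "a class has fewer than two rows"
        return rep

    if categorical:
        levels = sorted(set(values))
        table = np.array([[np.sum(g == lv) for lv in levels] for g in groups])
        if table.shape[1] < 2:
            rep.skipped = "single-level categorical descriptor"
            return rep
        chi2, p, _, _ = sps.chi2_contingency(table)
        rep.statistic, rep.p_value = float(chi2), float(p)
        for c, g in zip(classes, groups):
            rep.class_stats[c] = (float("nan"), float("nan"), len(g))
        return rep

    for c, g in zip(classes, groups):
        rep.class_stats[c] = (float(np.mean(g)), float(np.std(g, ddof=1)), len(g))
    if all(np.allclose(g, groups[0][0]) for g in groups):
        rep.skipped = "zero within-class variance for all classes"
        return rep
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        F, p = sps.f_oneway(*groups)
    rep.statistic, rep.p_value = float(F), float(p)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            ga, gb = values[labels == a], values[labels == b]
            with np.errstate(invalid="ignore", divide="ignore"), \
                    _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                t, praw = sps.ttest_ind(ga, gb)
            rep.pairwise[(a, b)] = {
                "t": float(t), "p_raw": float(praw),
                "p_bonferroni": float(min(1.0, praw * n_comparisons)),
            }
    return rep


def comparison_table(X: pd.DataFrame, labels: Sequence[str],
                     n_comparisons: int | None = None) -> pd.DataFrame:
    """Run :func:`class_comparison` for every column of ``X``.

    The Bonferroni denominator defaults to the number of descriptors in
    the family (the column count).  Returns a tidy frame with one row per
    descriptor: ANOVA F/p, the minimum Bonferroni-corrected pairwise p,
    and per-class mean +- sd columns.
    """
    n_classes = len(set(labels))
    if n_comparisons is None:
        # correct over every test performed: descriptors x class pairs;
        # correcting over descriptors alone does not control the
        # family-wise error once three classes are compared
        n_comparisons = X.shape[1] * max(1, n_classes * (n_classes - 1) // 2)
    rows = []
    classes = sorted(set(labels))
    for col in X.columns:
        rep = class_comparison(X[col].to_numpy(), labels, descriptor=col,
                               n_comparisons=n_comparisons)
        row: dict = {"descriptor": col, "F": rep.statistic, "p": rep.p_value,
                     "skipped": rep.skipped}
        if rep.pairwise:
            row["min_p_bonferroni"] = min(d["p_bonferroni"]
                                          for d in rep.pairwise.values())
        else:
            row["min_p_bonferroni"] = float("nan")
        for c in classes:
            mean, sd, n = rep.class_stats.get(c, (float("nan"), float("nan"), 0))
            row[f"mean_{c}"] = mean
            row[f"sd_{c}"] = sd
            row[f"n_{c}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-aware folds and balancing

def cv_split(dataset: GroupedDataset, n_folds: int = 5, seed: int = 0
             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-level fold assignment: all rows of one group share a fold.

    Unique groups are shuffled deterministically under ``seed`` and dealt
    round-robin so folds are balanced by group count.  Returns
    (train_idx, test_idx) pairs; fewer groups than folds is an error.
    """
    uniq = np.array(sorted(set(dataset.groups)))
    if len(uniq) < n_folds:
        raise ValueError(f"need >= {n_folds} groups, have {len(uniq)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: i % n_folds for i, g in enumerate(perm)}
    fold_per_row = np.array([fold_of_group[g] for g in dataset.groups])
    folds = []
    for f in range(n_folds):
        test = np.where(fold_per_row == f)[0]
        train = np.where(fold_per_row != f)[0]
        folds.append((train, test))
    return folds


def balance_classes(dataset: GroupedDataset, seed: int = 0) -> GroupedDataset:
    """Random group-level undersampling of the majority class to a 1:1
    group ratio.  The retained majority groups are a random subset of the
    original ones; deterministic under ``seed``."""
    classes = sorted(set(dataset.y))
    if len(classes) != 2:
        raise ValueError("balance_classes expects exactly two classes")
    group_class: dict = {}
    for g, c in zip(dataset.groups, dataset.y):
        prev = group_class.setdefault(g, c)
        if prev != c:
            raise ValueError(f"group {g} spans multiple classes")
    by_class = {c: sorted(g for g, gc in group_class.items() if gc == c)
                for c in classes}
    if any(len(v) == 0 for v in by_class.values()):
        raise ValueError("a class has zero groups")
    n_keep = min(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    keep: set = set()
    for c in classes:
        groups = by_class[c]
        chosen = rng.choice(len(groups), size=n_keep, replace=False)
        keep.update(groups[i] for i in chosen)
    idx = np.where([g in keep for g in dataset.groups])[0]
    return dataset.subset(idx)


# ---------------------------------------------------------------------------
# CART

@dataclass
class CartReport:
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    n_evaluations: int
    tree: DecisionTreeClassifier
    feature_names: list[str]
    positive_label: str
    tree_text: str
    tree_json: dict
    dropped_features: list[str] = field(default_factory=list)


def _prune_alpha(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 min_leaf: int, seed: int, max_alphas: int = 8) -> float:
    """Pick a cost-complexity alpha by an internal group-aware holdout."""
    base = DecisionTreeClassifier(min_samples_leaf=min_leaf, random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(path.ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) <= 1:
        return 0.0
    if len(alphas) > max_alphas:
        alphas = alphas[np.linspace(0, len(alphas) - 2, max_alphas).astype(int)]
    uniq = np.array(sorted(set(groups)))
    rng = np.random.default_rng(seed)
    heldout_groups = set(uniq[rng.permutation(len(uniq))[:max(1, len(uniq) // 4)]])
    mask = np.array([g in heldout_groups for g in groups])
    if mask.all() or not mask.any():
        return 0.0
    best_alpha, best_score = 0.0, -1.0
    for a in alphas:
        clf = DecisionTreeClassifier(min_samples_leaf=min_leaf,
                                     random_state=seed, ccp_alpha=float(a))
        clf.fit(X[~mask], y[~mask])
        score = clf.score(X[mask], y[mask])
        if score > best_score + 1e-12:
            best_alpha, best_score = float(a), score
    return best_alpha


def cart_train_eval(dataset: GroupedDataset, n_folds: int = 5,
                    repeats: int = 500, seed: int = 0,
                    positive_label: str | None = None,
                    min_samples_leaf: int = 5, prune: bool = True,
                    balance: bool = True) -> CartReport:
    """Balanced, group-aware cross-validated CART for two classes.

    Per repeat: (optionally) rebalance the classes at group granularity,
    deal groups into ``n_folds`` folds, fit a Gini CART per fold
    (cost-complexity-pruned via an internal holdout) and score the
    held-out fold.  Reports mean +- sd sensitivity / specificity /
    accuracy / precision_eq5 over folds x repeats plus a final tree
    fitted on the full (balanced) data.  Constant features are dropped
    with a note; unsplittable folds fall back to a majority-class stump.
    """
    classes = sorted(set(dataset.y))
    if len(classes) != 2:
        raise ValueError("cart_train_eval expects exactly two classes")
    if positive_label is None:
        positive_label = classes[-1]
    feature_names = list(dataset.X.columns)
    Xfull = dataset.X.to_numpy(dtype=float)
    const = [feature_names[j] for j in range(Xfull.shape[1])
             if np.nanstd(Xfull[:, j]) == 0 or np.isnan(Xfull[:, j]).all()]
    kept_cols = [c for c in feature_names if c not in const]
    data = GroupedDataset(dataset.X[kept_cols], dataset.y, dataset.groups)

    per_fold: list[dict[str, float]] = []
    for r in range(repeats):
        rep_seed = seed + 1000 * r
        ds = balance_classes(data, seed=rep_seed) if balance else data
        folds = cv_split(ds, n_folds=n_folds, seed=rep_seed)
        Xa = ds.X.to_numpy(dtype=float)
        for train, test in folds:
            Xtr, ytr = Xa[train], ds.y[train]
            alpha = (_prune_alpha(Xtr, ytr, ds.groups[train],
                                  min_samples_leaf, rep_seed) if prune else 0.0)
            clf = DecisionTreeClassifier(min_samples_leaf=min_samples_leaf,
                                         random_state=rep_seed, ccp_alpha=alpha)
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xa[test])
            ytest = ds.y[test]
            c = ConfusionCounts(
                TP=int(np.sum((pred == positive_label) & (ytest == positive_label))),
                TN=int(np.sum((pred != positive_label) & (ytest != positive_label))),
                FP=int(np.sum((pred == positive_label) & (ytest != positive_label))),
                FN=int(np.sum((pred != positive_label) & (ytest == positive_label))))
            per_fold.append(performance_metrics(c))

    names = ["sensitivity", "specificity", "accuracy", "precision_eq5"]
    arr = {m: np.array([f[m] for f in per_fold]) for m in names}
    metrics_mean = {m: float(np.nanmean(v)) for m, v in arr.items()}
    metrics_sd = {m: float(np.nanstd(v)) for m, v in arr.items()}

    final_ds = balance_classes(data, seed=seed) if balance else data
    Xf = final_ds.X.to_numpy(dtype=float)
    alpha = (_prune_alpha(Xf, final_ds.y, final_ds.groups,
                          min_samples_leaf, seed) if prune else 0.0)
    tree = DecisionTreeClassifier(min_samples_leaf=min_samples_leaf,
                                  random_state=seed, ccp_alpha=alpha)
    tree.fit(Xf, final_ds.y)
    return CartReport(
        metrics_mean=metrics_mean, metrics_sd=metrics_sd,
        n_evaluations=len(per_fold), tree=tree, feature_names=kept_cols,
        positive_label=positive_label,
        tree_text=export_text(tree, feature_names=kept_cols),
        tree_json=_tree_to_json(tree, kept_cols),
        dropped_features=const)


def _tree_to_json(tree: DecisionTreeClassifier, feature_names: list[str]) -> dict:
    """Nested split structure with per-node class probabilities and the
    percentage of training rows reaching the node."""
    t = tree.tree_
    total = t.n_node_samples[0]
    classes = [str(c) for c in tree.classes_]

    def node(i: int) -> dict:
        counts = t.value[i][0] * t.weighted_n_node_samples[i]
        probs = (t.value[i][0] / t.value[i][0].sum()).tolist()
        d = {
            "node_pct": round(100.0 * t.n_node_samples[i] / total, 1),
            "class_probabilities": dict(zip(classes, [round(p, 4) for p in probs])),
            "majority_class": classes[int(np.argmax(counts))],
        }
        if t.children_left[i] >= 0:
            d["split"] = {"feature": feature_names[t.feature[i]],
                          "threshold": round(float(t.threshold[i]), 6)}
            d["left"] = node(t.children_left[i])
            d["right"] = node(t.children_right[i])
        return d

    return node(0)
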