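"""Training, selection and interpretation of the tree-based classifiers.

Three algorithms are supported, all in their scikit-learn formulation:
a single CART decision tree (DT), extremely randomized trees (ET, 500
trees by default) and gradient-boosted trees (GT, 1000 trees by
default).  Model selection maximizes the F1-score with the Epitope
class as positive, averaged over repeated stratified cross-validation
on each of the training sets of a split plan.  Interpretation helpers
expose normalized mean-decrease-in-impurity (MDI) feature importances,
structural complexity counts and, for the decision tree, explicit
root-to-leaf classification rules for pure Epitope leaves.  A
K-nearest-neighbour baseline over the standardized descriptors is
included for comparison on redundant datasets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataset import SplitPlan
from .descriptors import FEATURE_NAMES

POSITIVE_LABEL = "Epitope"
NEGATIVE_LABEL = "Nonepitope"

ALGORITHMS = ("DT", "ET", "GT")

#: Default hyperparameter grids; ET/GT tree counts follow the shipped
#: model family (single tree, 500 extra trees, 1000 boosted trees).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [5, 8, 11, None], "min_samples_leaf": [1, 3, 5]},
    "ET": {"n_estimators": [500], "min_samples_leaf": [1, 3]},
    "GT": {"n_estimators": [1000], "max_depth": [3], "learning_rate": [0.1]},
}


@dataclass
class HyperGrid:
    algorithm: str
    grid: dict[str, list]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def combinations(self) -> list[dict]:
        from sklearn.model_selection import ParameterGrid

        return list(ParameterGrid(self.grid))


@dataclass
class TrainedModel:
    algorithm: str
    params: dict
    estimator: object
    seed: int
    dataset_hash: str
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass
class EvalReport:
    """Precision / recall / F1 (Epitope positive) means and sds."""

    train_precision: float
    train_recall: float
    train_f1: float
    train_f1_sd: float
    test_precision: float
    test_recall: float
    test_f1: float
    test_f1_sd: float
    extra: dict = field(default_factory=dict)


def make_estimator(algorithm: str, params: Mapping | None = None, seed: int = 0):
    from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
    from sklearn.tree import DecisionTreeClassifier

    params = dict(params or {})
    if algorithm == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **params)
    if algorithm == "ET":
        params.setdefault("n_estimators", 500)
        return ExtraTreesClassifier(random_state=seed, **params)
    if algorithm == "GT":
        params.setdefault("n_estimators", 1000)
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _dataset_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(",".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def _f1_scorer():
    from sklearn.metrics import make_scorer, f1_score

    return make_scorer(f1_score, pos_label=POSITIVE_LABEL, zero_division=0)


def grid_select(
    X: np.ndarray,
    y: Sequence[str],
    splits: SplitPlan,
    grid: HyperGrid,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Pick the combination maximizing mean CV F1 over all training sets.

    For every hyperparameter combination, each training set of the
    split plan is scored by ``cv_repeats`` repetitions of stratified
    ``cv_folds``-fold cross-validation; the winner maximizes the grand
    mean F1 (Epitope positive).  Ties keep the first-listed combination.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    combos = grid.combinations()
    scorer = _f1_scorer()
    best: tuple[float, int] | None = None
    best_params: dict = {}
    for ci, params in enumerate(combos):
        fold_means = []
        for train_idx, _ in splits.pairs:
            est = make_estimator(grid.algorithm, params, seed=seed)
            cv = RepeatedStratifiedKFold(
                n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
            )
            scores = cross_val_score(
                est, X[train_idx], y[train_idx], cv=cv, scoring=scorer
            )
            fold_means.append(scores.mean())
        mean_f1 = float(np.mean(fold_means))
        if best is None or mean_f1 > best[0]:
            best = (mean_f1, ci)
            best_params = params
    return best_params


def train_final(
    X: np.ndarray,
    y: Sequence[str],
    algorithm: str,
    params: Mapping | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one model on the full dataset, deterministically for a seed."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = make_estimator(algorithm, params, seed=seed)
    est.fit(X, y)
    return TrainedModel(algorithm, dict(params or {}), est, seed, _dataset_hash(X, y))


def predict_patch(model: TrainedModel, descriptors) -> float:
    """Probability that a patch is an Epitope, in [0, 1].

    DT: class fraction of the reached leaf; ET: average over trees;
    GT: logistic-transformed boosted score (scikit-learn's
    ``predict_proba``).
    """
    x = _as_feature_row(descriptors)
    proba = model.estimator.predict_proba(x)
    classes = list(model.estimator.classes_)
    return float(proba[0][classes.index(POSITIVE_LABEL)])


def predict_many(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(POSITIVE_LABEL)]


def _as_feature_row(descriptors) -> np.ndarray:
    if hasattr(descriptors, "as_array"):
        arr = descriptors.as_array()
    else:
        arr = np.asarray(descriptors, dtype=np.float64)
    if arr.ndim == 1:
        if arr.shape[0] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got {arr.shape[0]}"
            )
        arr = arr[None, :]
    if not np.isfinite(arr).all():
        raise ValueError("descriptor vector contains missing/non-finite features")
    return arr


def evaluate(model: TrainedModel, X, y) -> dict[str, float]:
    """Precision, recall and F1 with Epitope as positive class."""
    from sklearn.metrics import precision_recall_fscore_support

    pred = model.estimator.predict(np.asarray(X, dtype=np.float64))
    p, r, f1, _ = precision_recall_fscore_support(
        np.asarray(y), pred, pos_label=POSITIVE_LABEL, average="binary",
        zero_division=0,
    )
    return {"precision": float(p), "recall": float(r), "f1": float(f1)}


def mdi_importance(model: TrainedModel) -> tuple[np.ndarray, np.ndarray]:
    """Normalized MDI feature importances and their std over trees.

    Importances are non-negative and sum to 1; the std is zero for the
    single decision tree.
    """
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError("model is not fitted")
    imp = np.asarray(est.feature_importances_, dtype=float)
    trees = _trees_of(model)
    if len(trees) > 1:
        per_tree = np.array([t.tree_.compute_feature_importances() for t in trees])
        sums = per_tree.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        std = (per_tree / sums).std(axis=0)
    else:
        std = np.zeros_like(imp)
    return imp, std


def _trees_of(model: TrainedModel) -> list:
    est = model.estimator
    if model.algorithm == "DT":
        return [est]
    if model.algorithm == "ET":
        return list(est.estimators_)
    return [t for row in est.estimators_ for t in row]  # GT: (n_stages, n_classes-1)


def model_complexity(model: TrainedModel) -> dict[str, float]:
    """Tree count, node totals, mean nodes/depth per tree and leaf count."""
    trees = _trees_of(model)
    nodes = [t.tree_.node_count for t in trees]
    depths = [t.tree_.max_depth for t in trees]
    leaves = [t.tree_.n_leaves for t in trees]
    return {
        "n_trees": len(trees),
        "total_nodes": int(np.sum(nodes)),
        "mean_nodes_per_tree": float(np.mean(nodes)),
        "mean_depth": float(np.mean(depths)),
        "n_leaves": int(np.sum(leaves)),
    }


@dataclass
class Rule:
    """Conjunction of threshold conditions leading to one pure leaf."""

    conditions: list[str]
    label: str
    n_samples: int


def extract_rules(model: TrainedModel, min_samples: int = 3) -> list[Rule]:
    """Root-to-leaf rules for pure Epitope leaves of a decision tree.

    Returns one rule per pure Epitope leaf with at least ``min_samples``
    training samples, sorted by descending leaf population.
    """
    if model.algorithm != "DT":
        raise ValueError("rule extraction is only defined for the decision tree")
    tree = model.estimator.tree_
    classes = list(model.estimator.classes_)
    pos = classes.index(POSITIVE_LABEL)
    names = model.feature_names
    rules: list[Rule] = []

    def walk(node: int, conditions: list[str]) -> None:
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:  # leaf
            counts = tree.value[node][0] * tree.weighted_n_node_samples[node]
            n = int(round(counts.sum()))
            if counts[pos] > 0 and counts.sum() == counts[pos] and n >= min_samples:
                rules.append(Rule(list(conditions), POSITIVE_LABEL, n))
            return
        f, thr = names[tree.feature[node]], tree.threshold[node]
        walk(left, conditions + [f"{f} <= {thr:.4g}"])
        walk(right, conditions + [f"{f} > {thr:.4g}"])

    walk(0, [])
    rules.sort(key=lambda r: -r.n_samples)
    return rules


def knn_baseline(
    X: np.ndarray,
    y: Sequence[str],
    splits: SplitPlan,
    k: int = 3,
    cv_folds: int = 10,
) -> EvalReport:
    """K-nearest-neighbour baseline over standardized descriptors.

    Intended for the redundant dataset where instance-based prediction
    can exploit near-duplicate patches; majority vote over the ``k``
    closest samples in Euclidean distance.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.metrics import precision_recall_fscore_support

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if k % 2 == 0:
        raise ValueError("k must be odd to avoid voting ties")
    if k >= len(y):
        raise ValueError("k must be smaller than the dataset")
    scorer = _f1_scorer()
    cv_scores, test_p, test_r, test_f = [], [], [], []
    for train_idx, test_idx in splits.pairs:
        pipe = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=0)
        cv_scores.append(
            cross_val_score(pipe, X[train_idx], y[train_idx], cv=cv, scoring=scorer).mean()
        )
        pipe.fit(X[train_idx], y[train_idx])
        pred = pipe.predict(X[test_idx])
        p, r, f1, _ = precision_recall_fscore_support(
            y[test_idx], pred, pos_label=POSITIVE_LABEL, average="binary",
            zero_division=0,
        )
        test_p.append(p)
        test_r.append(r)
        test_f.append(f1)
    return EvalReport(
        train_precision=float("nan"),
        train_recall=float("nan"),
        train_f1=float(np.mean(cv_scores)),
        train_f1_sd=float(np.std(cv_scores)),
        test_precision=float(np.mean(test_p)),
        test_recall=float(np.mean(test_r)),
        test_f1=float(np.mean(test_f)),
        test_f1_sd=float(np.std(test_f)),
        extra={"k": k},
    )
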