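"""Base learners: pruned decision tree and ridge-penalized logistic regression.

Each base model is trained on one balanced group restricted to one feature
subset and is named ``<SUBSETLETTERS>_g<GROUPID>`` (e.g. ``ABEHIJ_g56``).
The near-native class is the positive class everywhere.

The tree is a C4.5-family classifier: entropy splits, a minimum leaf size,
and reduced-error pruning against a held-out fold (1/``rep_folds`` of the
group, stratified) that selects the cost-complexity pruning strength
minimizing held-out error.  The confidence factor is carried in the config
for compatibility but, as in inducers that switch to reduced-error pruning,
does not drive the pruning when a pruning fold is in use.

The logistic model is an L2 (ridge) penalized fit with a vanishingly small
default penalty (1e-8), iterated to convergence.  Its logistic score (LGS)
is the linear predictor — a strictly monotone transform of the predicted
probability, so rankings by either are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .dataset import BalancedGroup, FeatureSubset

logger = logging.getLogger(__name__)

__all__ = [
    "DTConfig",
    "DTModel",
    "LGModel",
    "train_decision_tree",
    "train_ridge_logistic",
    "dt_predict_positive",
    "logistic_score",
]


@dataclass(frozen=True)
class DTConfig:
    confidence_factor: float = 0.25
    min_objects: int = 2
    rep_folds: int = 3


def _as_frame(group) -> pd.DataFrame:
    return group.frame if isinstance(group, BalancedGroup) else group


def _group_id(group) -> int:
    return group.group_id if isinstance(group, BalancedGroup) else 0


class _ArrayTree:
    """Flattened decision tree: array-based traversal, JSON-serializable."""

    def __init__(self, children_left, children_right, feature, threshold, leaf_class):
        self.children_left = np.asarray(children_left, dtype=np.int64)
        self.children_right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.leaf_class = np.asarray(leaf_class, dtype=bool)

    @classmethod
    def from_sklearn(cls, clf: DecisionTreeClassifier) -> "_ArrayTree":
        t = clf.tree_
        # leaf class = argmax over class counts, mapped through clf.classes_
        cls_idx = t.value.reshape(t.node_count, -1).argmax(axis=1)
        leaf_class = np.asarray(clf.classes_)[cls_idx].astype(bool)
        return cls(t.children_left, t.children_right, t.feature, t.threshold, leaf_class)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] >= 0
        while active.any():
            rows = np.nonzero(active)[0]
            nd = node[rows]
            go_left = X[rows, self.feature[nd]] <= self.threshold[nd]
            node[rows] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] >= 0
        return self.leaf_class[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_ArrayTree":
        return cls(d["children_left"], d["children_right"], d["feature"],
                   d["threshold"], np.asarray(d["leaf_class"], dtype=bool))


@dataclass
class DTModel:
    subset: FeatureSubset
    group_id: int
    tree: _ArrayTree
    config: DTConfig = field(default_factory=DTConfig)

    @property
    def model_name(self) -> str:
        return f"{self.subset.name}_g{self.group_id}"

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        return self.tree.predict(df[self.subset.columns].to_numpy(dtype=float))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "ankplex-dt/1",
            "model_name": self.model_name,
            "subset": self.subset.name,
            "group_id": self.group_id,
            "config": vars(self.config) | {},
            "tree": self.tree.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DTModel":
        d = json.loads(Path(path).read_text())
        return cls(
            subset=FeatureSubset(d["subset"]),
            group_id=d["group_id"],
            tree=_ArrayTree.from_dict(d["tree"]),
            config=DTConfig(**d["config"]),
        )


@dataclass
class LGModel:
    subset: FeatureSubset
    group_id: int
    weights: np.ndarray
    intercept: float
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.subset):
            raise ValueError("one weight per subset feature required")
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.intercept)):
            raise ValueError("non-finite logistic weights")

    @property
    def model_name(self) -> str:
        return f"{self.subset.name}_g{self.group_id}"

    def score_df(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.subset.columns].to_numpy(dtype=float)
        return X @ self.weights + self.intercept

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        return self.score_df(df) > 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "ankplex-lg/1",
            "model_name": self.model_name,
            "subset": self.subset.name,
            "group_id": self.group_id,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "ridge": self.ridge,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LGModel":
        d = json.loads(Path(path).read_text())
        return cls(
            subset=FeatureSubset(d["subset"]),
            group_id=d["group_id"],
            weights=np.asarray(d["weights"]),
            intercept=d["intercept"],
            ridge=d["ridge"],
        )


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if y.all() or not y.any():
        raise ValueError(f"{what}: training group contains a single class")


def train_decision_tree(
    group,
    subset: FeatureSubset,
    config: DTConfig | None = None,
    seed: int = 0,
) -> DTModel:
    """Fit a pruned decision tree on a balanced group over one feature subset.

    Deterministic given ``seed``: the held-out pruning fold, the tree
    inducer's tie-breaking and the pruning-strength selection are all seeded
    or deterministic.
    """
    config = config or DTConfig()
    df = _as_frame(group)
    X = df[subset.columns].to_numpy(dtype=float)
    y = df["is_near_native"].to_numpy(dtype=bool)
    _check_two_classes(y, "train_decision_tree")

    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=1.0 / config.rep_folds, random_state=seed
    )
    grow_idx, prune_idx = next(splitter.split(X, y))

    def fit(alpha: float) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=config.min_objects,
            ccp_alpha=alpha,
            random_state=seed,
        ).fit(X[grow_idx], y[grow_idx])

    full = fit(0.0)
    alphas = np.unique(full.cost_complexity_pruning_path(X[grow_idx], y[grow_idx]).ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) > 12:  # cap candidate pruning strengths; quantile-spaced
        alphas = np.unique(np.quantile(alphas, np.linspace(0, 1, 12)))
    best_alpha, best_err = 0.0, np.inf
    for alpha in alphas:
        clf = full if alpha == 0.0 else fit(alpha)
        err = float(np.mean(clf.predict(X[prune_idx]) != y[prune_idx]))
        # ties resolved toward the stronger pruning (simpler tree)
        if err < best_err or (err == best_err and alpha > best_alpha):
            best_alpha, best_err = float(alpha), err
    final = full if best_alpha == 0.0 else fit(best_alpha)
    return DTModel(
        subset=subset,
        group_id=_group_id(group),
        tree=_ArrayTree.from_sklearn(final),
        config=config,
    )


def train_ridge_logistic(
    group,
    subset: FeatureSubset,
    ridge: float = 1e-8,
    max_iter: int = 10_000,
) -> LGModel:
    """Fit the ridge-penalized logistic model on a balanced group.

    The penalty (default 1e-8) is nominal — it guarantees a finite optimum
    even under complete separation — and the fit iterates to convergence,
    with a hard cap of ``max_iter`` iterations treated as non-convergence.
    """
    df = _as_frame(group)
    X = df[subset.columns].to_numpy(dtype=float)
    y = df["is_near_native"].to_numpy(dtype=bool)
    _check_two_classes(y, "train_ridge_logistic")
    if ridge <= 0:
        raise ValueError("ridge must be positive")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-6)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"ridge logistic fit did not converge within {max_iter} iterations"
            ) from exc
    # classes_ is [False, True]: decision_function is the log-odds of near-native
    return LGModel(
        subset=subset,
        group_id=_group_id(group),
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        ridge=ridge,
    )


def _row_to_array(model_subset: FeatureSubset, features) -> np.ndarray:
    if isinstance(features, pd.Series) or isinstance(features, Mapping):
        try:
            vals = [features[c] for c in model_subset.columns]
        except KeyError as exc:
            raise ValueError(f"feature vector missing {exc.args[0]!r}") from None
    else:  # FeatureVector
        vals = [features[letter] for letter in model_subset.letters]
    arr = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature vector has missing/non-finite values")
    return arr


def dt_predict_positive(model: DTModel, features) -> bool:
    """Boolean near-native prediction for one feature vector."""
    arr = _row_to_array(model.subset, features)
    return bool(model.tree.predict(arr[None, :])[0])


def logistic_score(model: LGModel, features) -> float:
    """LGS: the linear predictor intercept + Σ wᵢ·xᵢ (higher = more native-like)."""
    arr = _row_to_array(model.subset, features)
    return float(arr @ model.weights + model.intercept)
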