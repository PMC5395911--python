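"""Cross-validated metrics and feature-importance analysis.

Metrics follow the usual confusion-matrix definitions, in percent:
accuracy (TP+TN)/(TP+TN+FP+FN)·100, sensitivity TP/(TP+FN)·100, precision
TP/(TP+FP)·100.  Precision with TP+FP = 0 is undefined and reported missing
(NaN), never silently as 0.  Cross-validation is stratified — at a 1:66
class imbalance unstratified folds routinely lose the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .scoring import FEATURE_NAMES
from .dataset import FeatureSubset
from .learners import DTConfig, DTModel, LGModel, train_decision_tree, train_ridge_logistic

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "accuracy",
    "sensitivity",
    "precision",
    "cross_validate",
    "feature_weight_correlation",
    "class_feature_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined without positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """Precision in percent; NaN when no positive predictions were made."""
    if c.tp + c.fp == 0:
        return float("nan")
    return 100.0 * c.tp / (c.tp + c.fp)


@dataclass
class CVReport:
    folds: int
    counts: list[ConfusionCounts]
    acc_mean: float
    acc_sd: float
    sen_mean: float
    sen_sd: float
    pres_mean: float
    pres_sd: float

    def as_row(self) -> dict:
        return {
            "PRES(%)": f"{self.pres_mean:.2f} ± {self.pres_sd:.2f}",
            "REC(%)": f"{self.sen_mean:.2f} ± {self.sen_sd:.2f}",
            "ACC(%)": f"{self.acc_mean:.2f} ± {self.acc_sd:.2f}",
        }


def _fit_predictor(train_df: pd.DataFrame, learner_config: dict, seed: int):
    kind = learner_config.get("kind", "lg")
    subset = learner_config.get("subset") or FeatureSubset("ABCDEFGHIJK")
    if isinstance(subset, str):
        subset = FeatureSubset(subset)
    if kind == "dt":
        model = train_decision_tree(
            train_df, subset, config=learner_config.get("dt_config") or DTConfig(), seed=seed
        )
    elif kind == "lg":
        model = train_ridge_logistic(train_df, subset, ridge=learner_config.get("ridge", 1e-8))
    else:
        raise ValueError(f"unknown learner kind {kind!r}")
    return model


def cross_validate(
    dataset: pd.DataFrame,
    learner_config: dict,
    folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of one base learner.

    ``learner_config``: ``{"kind": "dt"|"lg", "subset": FeatureSubset|str,
    "dt_config": DTConfig, "ridge": float}``.  Every fold must retain both
    classes.  Fold means are over folds where the metric is defined.
    """
    y = dataset["is_near_native"].to_numpy(dtype=bool)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    counts: list[ConfusionCounts] = []
    accs, sens, press = [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        y_test = y[test_idx]
        if y_test.all() or not y_test.any():
            raise ValueError("a stratified fold lost one class; reduce fold count")
        model = _fit_predictor(dataset.iloc[train_idx], learner_config, seed)
        pred = model.predict_df(dataset.iloc[test_idx])
        c = ConfusionCounts(
            tp=int((pred & y_test).sum()),
            tn=int((~pred & ~y_test).sum()),
            fp=int((pred & ~y_test).sum()),
            fn=int((~pred & y_test).sum()),
        )
        counts.append(c)
        accs.append(accuracy(c))
        sens.append(sensitivity(c))
        press.append(precision(c))
    press_arr = np.asarray(press)
    return CVReport(
        folds=folds,
        counts=counts,
        acc_mean=float(np.mean(accs)),
        acc_sd=float(np.std(accs, ddof=1)),
        sen_mean=float(np.mean(sens)),
        sen_sd=float(np.std(sens, ddof=1)),
        pres_mean=float(np.nanmean(press_arr)),
        pres_sd=float(np.nanstd(press_arr, ddof=1)),
    )


def feature_weight_correlation(lg: LGModel, rows: pd.DataFrame) -> dict[str, float]:
    """Pearson R between each weighted feature contribution and the LGS.

    For every feature i in the model's subset the contribution wᵢ·xᵢ is
    correlated across rows (typically the near-native poses) with the total
    logistic score.  Zero-variance contributions are reported as NaN.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows")
    X = rows[lg.subset.columns].to_numpy(dtype=float)
    lgs = X @ lg.weights + lg.intercept
    if np.std(lgs) == 0:
        raise ValueError("LGS has zero variance over these rows")
    out: dict[str, float] = {}
    for i, col in enumerate(lg.subset.columns):
        contrib = lg.weights[i] * X[:, i]
        if np.std(contrib) == 0:
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(contrib, lgs)[0])
    return out


def class_feature_summary(
    dataset: pd.DataFrame,
    test: Literal["welch", "mannwhitney"] = "welch",
) -> pd.DataFrame:
    """Per-feature mean ± sd by class with a two-sample test p-value.

    The default test is Welch's unequal-variance t-test; Mann–Whitney U is
    available for a rank-based alternative.
    """
    y = dataset["is_near_native"].to_numpy(dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 rows per class")
    rows = []
    for col in FEATURE_NAMES:
        pos = dataset.loc[y, col].to_numpy(dtype=float)
        neg = dataset.loc[~y, col].to_numpy(dtype=float)
        if test == "welch":
            p = float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
        rows.append(
            {
                "feature": col,
                "near_native_mean": pos.mean(),
                "near_native_sd": pos.std(ddof=1),
                "non_near_native_mean": neg.mean(),
                "non_near_native_sd": neg.std(ddof=1),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
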