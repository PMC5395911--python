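"""The two-stage re-scoring rule and ensemble model-pair search.

Re-scoring one complex with a (DT, LG) pair:

1. keep only the poses the decision tree predicts positive (PPV_DT);
2. compute the logistic score (LGS) of each kept pose;
3. rank by LGS descending (ties by pose id ascending) and take the top 10.

A complex scores Y = 1 when a true near-native pose appears in the top 10;
``#PP`` over a complex set is Σ Y.  The pair search evaluates candidate
(DT, LG) combinations from the retained model pools and maximizes the
lexicographic objective (#PP on training complexes, #PP on test complexes,
lower mean first-true-positive rank).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .scoring import FEATURE_NAMES
from .learners import DTModel, LGModel

logger = logging.getLogger(__name__)

__all__ = [
    "RankingResult",
    "PPScore",
    "tprate_select",
    "ankplex_rescore",
    "compute_pp",
    "rank_by_single_feature",
    "search_ensemble",
]


@dataclass
class RankingResult:
    complex_id: str
    ranked_poses: list[tuple[str, float]]
    top10: list[tuple[str, float]]
    first_tp_rank: int | None
    n_tp_top10: int
    Y: int

    def __post_init__(self) -> None:
        if self.Y != int(self.n_tp_top10 >= 1):
            raise ValueError("Y inconsistent with n_tp_top10")


@dataclass
class PPScore:
    pp: int
    per_complex_Y: dict[str, int]


def tprate(predictions: np.ndarray, labels: np.ndarray) -> float:
    """True-positive rate TP/(TP+FN)·100 of boolean predictions."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("evaluation rows contain no positives")
    predictions = np.asarray(predictions, dtype=bool)
    tp = int((predictions & labels).sum())
    fn = int((~predictions & labels).sum())
    return 100.0 * tp / (tp + fn)


def tprate_select(models: Sequence, eval_rows: pd.DataFrame, threshold: float = 50.0) -> list:
    """Keep models whose TPrate on ``eval_rows`` is ≥ ``threshold`` (inclusive)."""
    labels = eval_rows["is_near_native"].to_numpy(dtype=bool)
    if not labels.any():
        raise ValueError("evaluation rows contain no positives")
    kept = []
    for model in models:
        rate = tprate(model.predict_df(eval_rows), labels)
        logger.debug("model %s TPrate %.1f%%", model.model_name, rate)
        if rate >= threshold:
            kept.append(model)
    return kept


def _make_result(
    complex_id: str,
    pose_ids: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray | None,
    k: int,
) -> RankingResult:
    pose_ids = np.asarray(pose_ids, dtype=str)
    order = np.lexsort((pose_ids, -scores))  # LGS descending, pose_id ascending on ties
    ranked = [(str(pose_ids[i]), float(scores[i])) for i in order]
    top = ranked[:k]
    if labels is None or len(order) == 0:
        n_tp, first = 0, None
    else:
        lab_sorted = np.asarray(labels, dtype=bool)[order]
        n_tp = int(lab_sorted[:k].sum())
        first = int(np.argmax(lab_sorted)) + 1 if lab_sorted.any() else None
    return RankingResult(
        complex_id=complex_id,
        ranked_poses=ranked,
        top10=top,
        first_tp_rank=first,
        n_tp_top10=n_tp,
        Y=int(n_tp >= 1),
    )


def ankplex_rescore(
    poses: pd.DataFrame, dt: DTModel, lg: LGModel, k: int = 10
) -> RankingResult:
    """Apply the DT-positive filter then LGS ranking to one complex's poses.

    ``poses`` is a feature table (canonical columns); if an ``is_near_native``
    column is present, the true-positive statistics and Y are computed,
    otherwise they are reported as 0/None.  Zero DT-positives yield an empty
    ranking with Y = 0.
    """
    if poses.empty:
        raise ValueError("pose table is empty")
    complex_id = str(poses["complex_id"].iloc[0]) if "complex_id" in poses else ""
    mask = dt.predict_df(poses)
    kept = poses[mask]
    labels = kept["is_near_native"].to_numpy(dtype=bool) if "is_near_native" in kept else None
    return _make_result(
        complex_id,
        kept["pose_id"].to_numpy(dtype=object),
        lg.score_df(kept) if len(kept) else np.empty(0),
        labels,
        k,
    )


def compute_pp(results: Sequence[RankingResult]) -> PPScore:
    """#PP = Σ Y over one ranking result per complex."""
    per = {r.complex_id: r.Y for r in results}
    if len(per) != len(results):
        raise ValueError("multiple results for the same complex")
    return PPScore(pp=sum(per.values()), per_complex_Y=per)


#: features where a lower (more negative) energy is better; the composite
#: initial-docking score is the one ranked descending
_DESCENDING_FEATURES = {"ZDock"}


def rank_by_single_feature(
    poses: pd.DataFrame,
    feature: str,
    k: int = 10,
    orientation: Literal["auto", "ascending", "descending"] = "auto",
) -> RankingResult:
    """Rank one complex's poses by a single feature column and take the top k.

    ``auto`` ranks energies ascending (lower is better) and the composite
    docking score descending.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    if orientation == "auto":
        orientation = "descending" if feature in _DESCENDING_FEATURES else "ascending"
    vals = poses[feature].to_numpy(dtype=float)
    scores = vals if orientation == "descending" else -vals
    labels = poses["is_near_native"].to_numpy(dtype=bool) if "is_near_native" in poses else None
    complex_id = str(poses["complex_id"].iloc[0]) if "complex_id" in poses else ""
    return _make_result(complex_id, poses["pose_id"].to_numpy(dtype=object), scores, labels, k)


# ---------------------------------------------------------------------------
# pair search

@dataclass
class _ComplexView:
    complex_id: str
    rows: np.ndarray          # row indices into the combined frame
    labels: np.ndarray        # boolean near-native labels, pose_id-sorted


def _pair_objective(
    dt_mask: np.ndarray,
    lg_score: np.ndarray,
    views: Sequence[_ComplexView],
    k: int,
) -> tuple[int, float]:
    """(#PP, mean first-TP rank) of one (DT, LG) pair over a complex set."""
    pp = 0
    first_ranks = []
    for v in views:
        m = dt_mask[v.rows]
        if not m.any():
            first_ranks.append(np.inf)
            continue
        scores = lg_score[v.rows][m]
        labels = v.labels[m]
        order = np.argsort(-scores, kind="stable")  # rows pre-sorted by pose_id
        lab_sorted = labels[order]
        if lab_sorted[:k].any():
            pp += 1
        first_ranks.append(int(np.argmax(lab_sorted)) + 1 if lab_sorted.any() else np.inf)
    finite = [r for r in first_ranks if np.isfinite(r)]
    mean_first = float(np.mean(finite)) if finite else np.inf
    return pp, mean_first


def _views(df: pd.DataFrame) -> list[_ComplexView]:
    out = []
    for cid, sub in df.groupby("complex_id", sort=True):
        out.append(
            _ComplexView(
                complex_id=str(cid),
                rows=sub.index.to_numpy(),
                labels=sub["is_near_native"].to_numpy(dtype=bool),
            )
        )
    return out


def search_ensemble(
    dt_pool: Sequence[DTModel],
    lg_pool: Sequence[LGModel],
    train_rows: pd.DataFrame,
    test_rows: pd.DataFrame | None = None,
    budget: int | Literal["all"] = "all",
    seed: int = 0,
    k: int = 10,
    exhaustive_limit: int = 1_000_000,
    leaderboard_size: int = 100,
) -> tuple[DTModel, LGModel, pd.DataFrame]:
    """Search (DT, LG) pairs for the best re-scoring ensemble.

    Pairs are enumerated exhaustively when their number is within budget
    (``'all'`` caps at ``exhaustive_limit``), otherwise a seeded random
    sample of ``budget`` distinct pairs is drawn.  The objective is
    lexicographic: maximize #PP on the training complexes, then #PP on the
    test complexes, then minimize the mean rank of the first true positive
    on the training complexes.  Returns the best pair and a leaderboard.
    """
    if not dt_pool or not lg_pool:
        raise ValueError("model pools must be non-empty")
    combined = pd.concat(
        [train_rows, test_rows] if test_rows is not None else [train_rows], ignore_index=True
    )
    combined = combined.sort_values(["complex_id", "pose_id"], kind="stable").reset_index(drop=True)
    train_ids = set(train_rows["complex_id"].unique())
    views_trn = [v for v in _views(combined) if v.complex_id in train_ids]
    views_tst = [v for v in _views(combined) if v.complex_id not in train_ids]

    dt_masks = [m.predict_df(combined) for m in dt_pool]
    lg_scores = [m.score_df(combined) for m in lg_pool]

    n_pairs = len(dt_pool) * len(lg_pool)
    cap = exhaustive_limit if budget == "all" else int(budget)
    if n_pairs <= cap:
        pairs = list(itertools.product(range(len(dt_pool)), range(len(lg_pool))))
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_pairs, size=cap, replace=False)
        pairs = [(int(f // len(lg_pool)), int(f % len(lg_pool))) for f in flat]

    records = []
    best_key, best_pair = None, None
    for i, j in pairs:
        pp_trn, mean_first = _pair_objective(dt_masks[i], lg_scores[j], views_trn, k)
        pp_tst, _ = _pair_objective(dt_masks[i], lg_scores[j], views_tst, k) if views_tst else (0, np.inf)
        key = (pp_trn, pp_tst, -mean_first)
        records.append(
            {
                "dt_name": dt_pool[i].model_name,
                "lg_name": lg_pool[j].model_name,
                "pp_trn": pp_trn,
                "pp_test": pp_tst,
                "mean_first_tp_rank": mean_first,
            }
        )
        if best_key is None or key > best_key:
            best_key, best_pair = key, (i, j)

    leaderboard = (
        pd.DataFrame(records)
        .sort_values(
            ["pp_trn", "pp_test", "mean_first_tp_rank", "dt_name", "lg_name"],
            ascending=[False, False, True, True, True],
            kind="stable",
        )
        .head(leaderboard_size)
        .reset_index(drop=True)
    )
    assert best_pair is not None
    logger.info(
        "ensemble search: best pair %s + %s (pp_trn=%d, pp_test=%d)",
        dt_pool[best_pair[0]].model_name,
        lg_pool[best_pair[1]].model_name,
        best_key[0],
        best_key[1],
    )
    return dt_pool[best_pair[0]], lg_pool[best_pair[1]], leaderboard
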