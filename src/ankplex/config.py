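"""Run configuration and the end-to-end pipeline.

The full workflow is: label (or load/generate a labeled feature table) →
balance into negative groups → train DT and LG base models over a feature-
subset sweep → retain models with TPrate ≥ threshold → search (DT, LG)
pairs → re-score every complex with the best pair → evaluate.  Every output
artifact carries the config hash and seed so a rerun reproduces it
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import ensemble as ens
from .learners import DTConfig, train_decision_tree, train_ridge_logistic
from .evaluation import class_feature_summary, feature_weight_correlation
from .synthetic_data import DEFAULT_PROFILE, generate_suite

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Data source: either ``features_csv`` (a labeled feature table in the
    canonical schema) or the synthetic generator (``source='synthetic'``)
    with the given pose counts and pseudo-complex layout.
    """

    source: Literal["synthetic", "csv"] = "synthetic"
    features_csv: str | None = None
    test_complexes: list[str] = field(default_factory=list)
    # synthetic-source conditions
    n_pos: int = 669
    n_neg: int = 10_000
    n_train_complexes: int = 7
    n_test_complexes: int = 2
    # thresholds
    rmsd_cutoff: float = 10.0
    contact_cutoff: float = 5.0
    tprate_threshold: float = 50.0
    top_k: int = 10
    # learner parameters
    confidence_factor: float = 0.25
    min_objects: int = 2
    rep_folds: int = 3
    ridge: float = 1e-8
    # sweep and search
    subset_sweep: Literal["reduced", "full"] = "reduced"
    n_groups: int | Literal["auto"] = "auto"
    search_budget: int | Literal["all"] = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rmsd_cutoff", "contact_cutoff", "tprate_threshold", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    best_dt: object
    best_lg: object
    leaderboard: pd.DataFrame
    rankings: list
    pp_trn: int
    pp_test: int
    n_dt_pool: int
    n_lg_pool: int
    feature_summary: pd.DataFrame
    out_dir: Path | None


def _load_rows(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.source == "synthetic":
        return generate_suite(
            DEFAULT_PROFILE,
            n_pos=config.n_pos,
            n_neg=config.n_neg,
            n_train_complexes=config.n_train_complexes,
            n_test_complexes=config.n_test_complexes,
            seed=config.seed,
        )
    if not config.features_csv:
        raise ValueError("source='csv' requires features_csv")
    path = Path(config.features_csv)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = ds.validate_feature_table(pd.read_csv(path))
    test_ids = set(config.test_complexes)
    train = df[~df["complex_id"].isin(test_ids)].reset_index(drop=True)
    test = df[df["complex_id"].isin(test_ids)].reset_index(drop=True)
    return train, test


def _header(config: RunConfig) -> str:
    return f"# ankplex run config_hash={config.config_hash} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and optionally write artifacts to ``out_dir``.

    Returns the trained best pair, the search leaderboard, the per-complex
    re-scoring results and summary statistics.  Fully reproducible from the
    config (including its seed).
    """
    stage = "load"
    try:
        train_df, test_df = _load_rows(config)
        if train_df.empty:
            raise ValueError("no training rows")

        stage = "balance"
        groups = ds.build_balanced_groups(train_df, n_groups=config.n_groups, seed=config.seed)

        stage = "train"
        if config.subset_sweep == "reduced":
            subsets = ds.reduced_subset_sweep()
        else:
            subsets = ds.enumerate_feature_subsets(11)
        dt_cfg = DTConfig(
            confidence_factor=config.confidence_factor,
            min_objects=config.min_objects,
            rep_folds=config.rep_folds,
        )
        labels_trn = train_df["is_near_native"].to_numpy(dtype=bool)
        dt_pool, lg_pool = [], []
        for subset in subsets:
            for group in groups:
                dt = train_decision_tree(group, subset, config=dt_cfg, seed=config.seed)
                lg = train_ridge_logistic(group, subset, ridge=config.ridge)
                for model, pool in ((dt, dt_pool), (lg, lg_pool)):
                    rate = ens.tprate(model.predict_df(train_df), labels_trn)
                    logger.info("trained %s %s TPrate=%.1f%%",
                                type(model).__name__, model.model_name, rate)
                    if rate >= config.tprate_threshold:
                        pool.append(model)
        if not dt_pool or not lg_pool:
            raise ValueError("no models passed the TPrate threshold")

        stage = "ensemble-search"
        best_dt, best_lg, leaderboard = ens.search_ensemble(
            dt_pool,
            lg_pool,
            train_df,
            test_df if not test_df.empty else None,
            budget=config.search_budget,
            seed=config.seed,
            k=config.top_k,
        )

        stage = "rescore"
        rankings = []
        for cid, sub in pd.concat([train_df, test_df], ignore_index=True).groupby("complex_id"):
            rankings.append(ens.ankplex_rescore(sub.reset_index(drop=True), best_dt, best_lg,
                                                k=config.top_k))
        train_ids = set(train_df["complex_id"].unique())
        pp_trn = ens.compute_pp([r for r in rankings if r.complex_id in train_ids]).pp
        pp_test = ens.compute_pp([r for r in rankings if r.complex_id not in train_ids]).pp

        stage = "evaluate"
        feature_summary = class_feature_summary(train_df)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        config=config,
        best_dt=best_dt,
        best_lg=best_lg,
        leaderboard=leaderboard,
        rankings=rankings,
        pp_trn=pp_trn,
        pp_test=pp_test,
        n_dt_pool=len(dt_pool),
        n_lg_pool=len(lg_pool),
        feature_summary=feature_summary,
        out_dir=None,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        best_dt.to_json(out / f"dt_{best_dt.model_name}.json")
        best_lg.to_json(out / f"lg_{best_lg.model_name}.json")
        _write_tsv(leaderboard, out / "leaderboard.tsv", config)
        rank_rows = [
            {
                "complex_id": r.complex_id,
                "rank": i + 1,
                "pose_id": pid,
                "lgs": lgs,
            }
            for r in rankings
            for i, (pid, lgs) in enumerate(r.top10)
        ]
        _write_tsv(pd.DataFrame(rank_rows), out / "top_rankings.tsv", config)
        _write_tsv(feature_summary.reset_index(), out / "feature_summary.tsv", config)
        report = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "pp_trn": pp_trn,
            "pp_test": pp_test,
            "best_dt": best_dt.model_name,
            "best_lg": best_lg.model_name,
            "n_dt_pool": len(dt_pool),
            "n_lg_pool": len(lg_pool),
            "per_complex": {
                r.complex_id: {
                    "Y": r.Y,
                    "n_tp_top10": r.n_tp_top10,
                    "first_tp_rank": r.first_tp_rank,
                }
                for r in rankings
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        result.out_dir = out
    return result
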