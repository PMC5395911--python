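"""Balanced training-set construction and feature-subset enumeration.

Docking decoy sets are heavily imbalanced (roughly 1 near-native pose per 66
non-near-native after the recognition-area filter).  Training sets are
balanced by partitioning the negatives into disjoint blocks and pairing every
block with the full positive set, so each group sees all positives and a
fresh slice of negatives.

Feature subsets are the non-empty subsets of the 11 feature letters; with 11
features there are 2¹¹ − 1 = 4,095 of them.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .scoring import FEATURE_LETTERS, FEATURE_NAMES, LETTER_TO_NAME

__all__ = [
    "FeatureSubset",
    "BalancedGroup",
    "enumerate_feature_subsets",
    "reduced_subset_sweep",
    "build_balanced_groups",
    "validate_feature_table",
    "load_reference_counts",
    "reference_count_summary",
]

#: required columns of every labeled feature table
TABLE_COLUMNS = ["pose_id", "complex_id", "is_near_native"] + FEATURE_NAMES


@dataclass(frozen=True)
class FeatureSubset:
    """A non-empty subset of the feature letters A–K, e.g. ``ABEHIJ``."""

    letters: str

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("feature subset must be non-empty")
        if sorted(set(self.letters)) != list(self.letters):
            raise ValueError(f"subset letters must be sorted and unique: {self.letters!r}")
        unknown = set(self.letters) - set("ABCDEFGHIJKLMNOPQRST")
        if unknown:
            raise ValueError(f"unknown feature letters: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return self.letters

    @property
    def columns(self) -> list[str]:
        """Canonical column names; only defined for the 11 letters A-K."""
        missing = set(self.letters) - set(FEATURE_LETTERS)
        if missing:
            raise ValueError(f"no canonical columns for letters {sorted(missing)}")
        return [LETTER_TO_NAME[c] for c in self.letters]

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class BalancedGroup:
    """All positives plus one disjoint block of negatives."""

    group_id: int
    positives: pd.DataFrame
    negatives: pd.DataFrame

    @property
    def frame(self) -> pd.DataFrame:
        return pd.concat([self.positives, self.negatives], ignore_index=True)


def enumerate_feature_subsets(n_features: int = 11) -> list[FeatureSubset]:
    """All 2ⁿ − 1 non-empty feature subsets in (size, lexicographic) order."""
    if not 1 <= n_features <= 20:
        raise ValueError("n_features must be in [1, 20]")
    letters = "ABCDEFGHIJKLMNOPQRST"[:n_features]
    out = []
    for r in range(1, n_features + 1):
        for combo in itertools.combinations(letters, r):
            out.append(FeatureSubset("".join(combo)))
    return out


def reduced_subset_sweep(extra: Sequence[str] = ("ABEHIJ", "CDFGHJ")) -> list[FeatureSubset]:
    """A demonstration-scale sweep: all 1- and 2-feature subsets plus the
    named multi-feature subsets of the reference ensemble (68 subsets by
    default), in place of the full 4,095-subset enumeration."""
    subsets = [s for s in enumerate_feature_subsets(11) if len(s) <= 2]
    for name in extra:
        sub = FeatureSubset("".join(sorted(set(name))))
        if sub not in subsets:
            subsets.append(sub)
    return subsets


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a labeled feature table for the canonical schema."""
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if not df["is_near_native"].map(lambda v: isinstance(v, (bool, np.bool_))).all():
        df = df.copy()
        df["is_near_native"] = df["is_near_native"].astype(bool)
    return df


def build_balanced_groups(
    dataset: pd.DataFrame,
    n_groups: int | Literal["auto"] = "auto",
    seed: int = 0,
) -> list[BalancedGroup]:
    """Partition the negatives into ``n_groups`` blocks, each paired with all
    positives.

    ``auto`` sets ``n_groups = floor(n_neg / n_pos)``.  The negatives are
    shuffled with ``seed`` and split into nearly equal blocks (sizes differ by
    at most one); blocks are disjoint and together cover every negative.
    """
    df = validate_feature_table(dataset)
    pos = df[df["is_near_native"]].reset_index(drop=True)
    neg = df[~df["is_near_native"]].reset_index(drop=True)
    if len(pos) == 0:
        raise ValueError("dataset has no near-native rows")
    if n_groups == "auto":
        n_groups = max(1, len(neg) // len(pos))
    if n_groups > len(neg):
        raise ValueError(f"n_groups={n_groups} exceeds number of negatives ({len(neg)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg))
    blocks = np.array_split(order, n_groups)
    return [
        BalancedGroup(group_id=g + 1, positives=pos, negatives=neg.iloc[idx].reset_index(drop=True))
        for g, idx in enumerate(blocks)
    ]


# ---------------------------------------------------------------------------
# reference screening counts shipped with the package

def load_reference_counts() -> dict:
    """Per-complex near-native pose counts of the training benchmark under the
    four screening stages (shape-complementarity-only docking, composite-score
    docking, recognition-area filter, top-2000 by ZRank)."""
    with (resources.files("ankplex.data") / "reference_counts.json").open() as fh:
        return json.load(fh)


def reference_count_summary() -> pd.DataFrame:
    """Mean/SD/total of near-native poses per complex for each screening stage."""
    data = load_reference_counts()
    rows = []
    for stage, counts in data["near_native"].items():
        arr = np.asarray(counts, dtype=float)
        rows.append(
            {
                "stage": stage,
                "total": int(arr.sum()),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "n_complexes": len(arr),
            }
        )
    return pd.DataFrame(rows).set_index("stage")
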