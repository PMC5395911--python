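"""Synthetic feature tables and toy complexes for end-to-end testing.

Real inputs to this pipeline are tens of thousands of docked, minimized and
scored poses per complex — hours of docking-suite compute.  The generator
reproduces the statistical structure the pipeline assumes instead: class-
conditional Gaussian feature vectors whose default per-class means and SDs
are the benchmark's published summary statistics for near-native vs
non-near-native ankyrin-protein poses, with the two structural identities
(ZRank = ZRankElec + ZRankSolv + ZRankVdw; E_RDock = E_sol + 0.9·E_elec2)
recomputed exactly from the drawn components.  Features are otherwise
independent by default — only marginals are published — and a correlation
matrix can be injected for stress tests.

The class imbalance of the real screen is roughly 1:66 (669 near-native vs
44,334 non-near-native poses across seven training complexes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import FEATURE_LETTERS, LETTER_TO_NAME
from .structures_io import Atom, Pose

__all__ = [
    "ClassProfile",
    "DEFAULT_PROFILE",
    "generate_pose_features",
    "generate_suite",
    "generate_toy_complex",
]

#: letters drawn directly from the class Gaussians; D and K are derived
_DRAWN = "ABCEFGHIJ"

#: benchmark per-class (mean, sd): {letter: ((nn_mean, nn_sd), (non_mean, non_sd))}
_TABLE_PROFILE = {
    "A": ((36.73, 6.32), (33.41, 4.87)),    # ZDock
    "B": ((8.22, 16.56), (29.17, 22.41)),   # ZRankElec
    "C": ((3.66, 6.99), (7.88, 10.10)),     # ZRankSolv
    "D": ((-54.03, 25.84), (-21.82, 31.33)),  # ZRank (derived: B+C+E)
    "E": ((-65.91, 20.44), (-58.87, 20.98)),  # ZRankVdw
    "F": ((-56.21, 57.81), (-47.46, 101.79)),  # E_vdw1
    "G": ((-1.05, 2.18), (-0.94, 2.37)),    # E_elec1
    "H": ((-70.01, 42.72), (-74.33, 43.00)),  # E_vdw2
    "I": ((-18.21, 8.85), (-8.18, 10.25)),  # E_elec2
    "J": ((4.43, 6.26), (9.07, 8.87)),      # E_sol
    "K": ((-11.96, 9.40), (1.72, 12.10)),   # E_RDock (derived: J+0.9·I)
}


@dataclass
class ClassProfile:
    """Per-feature (mean, sd) for each class plus an optional correlation.

    ``near_native`` / ``non_near_native`` map feature letters A–K to
    (mean, sd).  ``correlation``, when given, is a positive-semidefinite
    matrix over the drawn letters (ABCEFGHIJ) applied within each class;
    the identities for D and K are always recomputed from components.
    """

    near_native: dict[str, tuple[float, float]]
    non_near_native: dict[str, tuple[float, float]]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for cls in (self.near_native, self.non_near_native):
            for letter in FEATURE_LETTERS:
                if letter not in cls:
                    raise ValueError(f"profile missing feature {letter}")
                if cls[letter][1] < 0:
                    raise ValueError(f"negative sd for feature {letter}")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(_DRAWN), len(_DRAWN)):
                raise ValueError(f"correlation must be {len(_DRAWN)}x{len(_DRAWN)}")
            if np.linalg.eigvalsh((C + C.T) / 2).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")
            self.correlation = C


DEFAULT_PROFILE = ClassProfile(
    near_native={k: v[0] for k, v in _TABLE_PROFILE.items()},
    non_near_native={k: v[1] for k, v in _TABLE_PROFILE.items()},
)


def _draw_class(
    params: dict[str, tuple[float, float]],
    n: int,
    rng: np.random.Generator,
    correlation: np.ndarray | None,
) -> pd.DataFrame:
    means = np.array([params[c][0] for c in _DRAWN])
    sds = np.array([params[c][1] for c in _DRAWN])
    if correlation is None:
        Z = rng.standard_normal((n, len(_DRAWN)))
    else:
        L = np.linalg.cholesky(correlation + 1e-12 * np.eye(len(_DRAWN)))
        Z = rng.standard_normal((n, len(_DRAWN))) @ L.T
    X = means + sds * Z
    df = pd.DataFrame(X, columns=[LETTER_TO_NAME[c] for c in _DRAWN])
    # structural identities, exact by construction
    df[LETTER_TO_NAME["D"]] = (
        df[LETTER_TO_NAME["B"]] + df[LETTER_TO_NAME["C"]] + df[LETTER_TO_NAME["E"]]
    )
    df[LETTER_TO_NAME["K"]] = df[LETTER_TO_NAME["J"]] + 0.9 * df[LETTER_TO_NAME["I"]]
    return df[[LETTER_TO_NAME[c] for c in FEATURE_LETTERS]]


def generate_pose_features(
    profile: ClassProfile = DEFAULT_PROFILE,
    n_pos: int = 669,
    n_neg: int = 44_334,
    n_complexes: int = 7,
    seed: int = 0,
    complex_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a labeled feature table in the canonical schema.

    Rows are assigned round-robin to ``n_complexes`` complexes (default ids
    C1..Cn), separately for each class so every complex receives both.
    Reproducible from (profile, counts, seed).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be at least 1")
    if complex_ids is None:
        complex_ids = [f"C{i + 1}" for i in range(n_complexes)]
    if len(complex_ids) != n_complexes:
        raise ValueError("complex_ids length must equal n_complexes")
    rng = np.random.default_rng(seed)
    pos = _draw_class(profile.near_native, n_pos, rng, profile.correlation)
    neg = _draw_class(profile.non_near_native, n_neg, rng, profile.correlation)
    pos.insert(0, "is_near_native", True)
    neg.insert(0, "is_near_native", False)
    df = pd.concat([pos, neg], ignore_index=True)
    df.insert(0, "complex_id", [complex_ids[i % n_complexes] for i in range(len(df))])
    df.insert(0, "pose_id", [f"pose_{i:06d}" for i in range(len(df))])
    return df


def generate_suite(
    profile: ClassProfile = DEFAULT_PROFILE,
    n_pos: int = 669,
    n_neg: int = 10_000,
    n_train_complexes: int = 7,
    n_test_complexes: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate pseudo-training and pseudo-test complexes from one draw.

    Training complexes are named C1..Cn, test complexes U1..Um; rows are
    spread round-robin over all of them, then split by membership.
    """
    ids = [f"C{i + 1}" for i in range(n_train_complexes)] + [
        f"U{i + 1}" for i in range(n_test_complexes)
    ]
    df = generate_pose_features(
        profile, n_pos, n_neg, len(ids), seed=seed, complex_ids=ids
    )
    is_test = df["complex_id"].str.startswith("U")
    return df[~is_test].reset_index(drop=True), df[is_test].reset_index(drop=True)


# ---------------------------------------------------------------------------
# toy structures

_RESIDUE_CYCLE = ["LEU", "GLU", "ALA", "LYS", "SER", "ILE", "ASP", "VAL", "ASN", "PHE"]


def _build_chain(chain_id: str, n_res: int, origin: np.ndarray, rng: np.random.Generator,
                 serial_start: int, flip: bool = False) -> list[Atom]:
    atoms: list[Atom] = []
    serial = serial_start
    sign = -1.0 if flip else 1.0  # side chains point away from the interface
    for i in range(n_res):
        ca = origin + np.array([3.8 * i, 0.0, 0.0])
        resn = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        offsets = {
            "N": np.array([-1.2, sign * 0.8, 0.0]),
            "CA": np.zeros(3),
            "C": np.array([1.2, sign * 0.8, 0.0]),
            "O": np.array([1.4, sign * 1.9, 0.1]),
            "CB": np.array([0.0, sign * -1.5, 0.3]),
        }
        for name, off in offsets.items():
            jitter = rng.normal(scale=0.05, size=3)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name=resn,
                    chain_id=chain_id,
                    residue_seq=i + 1,
                    coords=ca + off + jitter,
                )
            )
            serial += 1
    return atoms


def generate_toy_complex(
    n_res_receptor: int = 10,
    n_res_ligand: int = 8,
    displacement: float = 0.0,
    seed: int = 0,
) -> tuple[Pose, Pose]:
    """Build an idealized reference complex and a rigidly displaced decoy.

    The receptor (chain A) and ligand (chain B) are parallel extended chains
    with backbones ~7 Å apart and closest interface contacts ~3.5 Å (no
    steric clashes); the decoy's ligand is translated by ``displacement`` Å
    perpendicular to the interface, so its ligand Cα-RMSD to the reference
    equals ``displacement`` by construction.
    """
    if min(n_res_receptor, n_res_ligand) < 3:
        raise ValueError("need at least 3 residues per chain")
    rng = np.random.default_rng(seed)
    receptor = _build_chain("A", n_res_receptor, np.zeros(3), rng, serial_start=1)
    ligand = _build_chain(
        "B", n_res_ligand, np.array([1.9, 7.0, 0.0]), rng, serial_start=1000, flip=True
    )
    reference = Pose(pose_id="reference", receptor_atoms=receptor, ligand_atoms=ligand)
    decoy = reference.translated_ligand([0.0, 0.0, float(displacement)], pose_id="decoy")
    return reference, decoy
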