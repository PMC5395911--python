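"""Pairwise energy features for docking poses.

Eleven features (letters A–K) describe one receptor–ligand pose:

====== ============ ==========================================================
letter column       definition
====== ============ ==========================================================
A      ZDock        composite initial-docking score  α·PSC + DE + β·ELEC
B      ZRankElec    long-range Coulomb term over charged side chains
C      ZRankSolv    atomic-contact-energy (ACE) desolvation
D      ZRank        B + C + E
E      ZRankVdw     6-12 Lennard-Jones sum over interface pairs < 5 Å
F      E_vdw1       E recomputed on the 1st minimized coordinate set
G      E_elec1      Coulomb (all charged atoms, 12 Å) on the 1st minimized set
H      E_vdw2       E recomputed on the 2nd minimized coordinate set
I      E_elec2      Coulomb (all charged atoms, 12 Å) on the 2nd minimized set
J      E_sol        ACE desolvation on the 2nd minimized set
K      E_RDock      J + 0.9·I
====== ============ ==========================================================

The engine computes every term from atomic coordinates and pluggable
parameter tables.  The bundled tables are a reduced, element-class
demonstration set of force-field magnitude; users reproduce a published force
field by supplying their own TSVs.  Grid-based shape complementarity (PSC) is
not recomputed here: feature A takes the docking program's PSC when
available, otherwise the documented contact-count proxy stands in.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures_io import Atom, Pose

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_LETTERS",
    "FEATURE_NAMES",
    "LETTER_TO_NAME",
    "NAME_TO_LETTER",
    "HYDROPHOBIC_RESIDUES",
    "CHARGED_RESIDUES",
    "ScoringParams",
    "FeatureVector",
    "load_default_params",
    "assign_force_field",
    "interface_pairs",
    "vdw_energy",
    "elec_energy",
    "ace_desolvation",
    "zrank_score",
    "zdock_score",
    "psc_proxy",
    "compute_features",
]

FEATURE_LETTERS = "ABCDEFGHIJK"
LETTER_TO_NAME = {
    "A": "ZDock",
    "B": "ZRankElec",
    "C": "ZRankSolv",
    "D": "ZRank",
    "E": "ZRankVdw",
    "F": "E_vdw1",
    "G": "E_elec1",
    "H": "E_vdw2",
    "I": "E_elec2",
    "J": "E_sol",
    "K": "E_RDock",
}
NAME_TO_LETTER = {v: k for k, v in LETTER_TO_NAME.items()}
#: canonical feature-column order of every feature table in the package
FEATURE_NAMES = [LETTER_TO_NAME[c] for c in FEATURE_LETTERS]

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
CHARGED_RESIDUES = {"ARG", "LYS", "ASP", "GLU", "HIS"}


# ---------------------------------------------------------------------------
# parameters

def _sym(key: tuple[str, str]) -> tuple[str, str]:
    return tuple(sorted(key))  # type: ignore[return-value]


@dataclass
class ScoringParams:
    """Weights, cutoffs and parameter tables of the energy engine.

    Defaults: ``alpha``/``beta`` are the composite-score weights 0.01 and
    0.06; the Coulomb constant is 332 kcal·Å/(mol·e²); the Lennard-Jones sum
    runs over pairs strictly closer than ``vdw_cutoff`` = 5 Å; ACE contacts
    use ``ace_cutoff`` = 6 Å (standard contact definition — the composite
    score's source does not fix one); minimized-pose electrostatics (G/I) use
    ``elec_min_cutoff`` = 12 Å while the long-range term B has no cutoff.
    """

    alpha: float = 0.01
    beta: float = 0.06
    coulomb_constant: float = 332.0
    vdw_cutoff: float = 5.0
    elec_rdock_weight: float = 0.9
    ace_cutoff: float = 6.0
    elec_min_cutoff: float = 12.0
    psc_contact_shell: float = 5.0
    vdw_table: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    charge_table: dict[tuple[str, str], float] = field(default_factory=dict)
    ace_table: dict[tuple[str, str], float] = field(default_factory=dict)
    default_charge: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.elec_rdock_weight) <= 0:
            raise ValueError("alpha, beta and elec_rdock_weight must be positive")
        for (ti, tj), (eps, sig) in list(self.vdw_table.items()):
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid vdW parameters for ({ti}, {tj})")
            self.vdw_table[_sym((ti, tj))] = (eps, sig)
        for key, val in list(self.ace_table.items()):
            self.ace_table[_sym(key)] = val


def _read_tsv(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#")


def load_default_params(**overrides) -> ScoringParams:
    """Load the reduced demonstration parameter tables shipped with the package."""
    data = resources.files("ankplex.data")
    vdw_df = _read_tsv(data / "vdw_params.tsv")
    chg_df = _read_tsv(data / "charges.tsv")
    ace_df = _read_tsv(data / "ace_params.tsv")
    return ScoringParams(
        vdw_table={
            _sym((r.type_i, r.type_j)): (float(r.epsilon), float(r.sigma))
            for r in vdw_df.itertuples()
        },
        charge_table={(r.residue, r.atom): float(r.charge) for r in chg_df.itertuples()},
        ace_table={_sym((r.class_i, r.class_j)): float(r.ace) for r in ace_df.itertuples()},
        **overrides,
    )


def load_params_from_tables(
    vdw_path: str | Path, charge_path: str | Path, ace_path: str | Path, **overrides
) -> ScoringParams:
    """Build :class:`ScoringParams` from user-supplied TSV tables."""
    vdw_df = _read_tsv(vdw_path)
    chg_df = _read_tsv(charge_path)
    ace_df = _read_tsv(ace_path)
    return ScoringParams(
        vdw_table={
            _sym((r.type_i, r.type_j)): (float(r.epsilon), float(r.sigma))
            for r in vdw_df.itertuples()
        },
        charge_table={(r.residue, r.atom): float(r.charge) for r in chg_df.itertuples()},
        ace_table={_sym((r.class_i, r.class_j)): float(r.ace) for r in ace_df.itertuples()},
        **overrides,
    )


def _ace_class(atom: Atom) -> str | None:
    """Map an atom to its ACE contact class; hydrogens carry no ACE class."""
    el = atom.element
    if el == "H":
        return None
    if el == "C":
        return "CH" if atom.residue_name in HYDROPHOBIC_RESIDUES else "CP"
    if el in ("N", "O", "S"):
        return el
    return "CP"


def assign_force_field(pose: Pose, params: ScoringParams) -> Pose:
    """Annotate every atom with its vdW type and partial charge (in place).

    The vdW type of the reduced table is the element symbol; charges come from
    the (residue, atom) table with a residue wildcard ``*`` for backbone
    atoms, falling back to ``params.default_charge``.
    """
    for atom in list(pose.receptor_atoms) + list(pose.ligand_atoms):
        atom.atom_type = atom.element if atom.element in ("H", "C", "N", "O", "S") else "C"
        q = params.charge_table.get((atom.residue_name, atom.name))
        if q is None:
            q = params.charge_table.get(("*", atom.name), params.default_charge)
        atom.charge = q
    return pose


# ---------------------------------------------------------------------------
# pair generation

def interface_pairs(
    pose: Pose, cutoff: float, heavy_only: bool = True
) -> list[tuple[Atom, Atom, float]]:
    """All cross-complex atom pairs strictly closer than ``cutoff`` Å.

    Only receptor–ligand pairs are generated; intra-chain pairs never enter
    the interface energies.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = [a for a in pose.receptor_atoms if not (heavy_only and a.element == "H")]
    lig = [a for a in pose.ligand_atoms if not (heavy_only and a.element == "H")]
    if not rec or not lig:
        return []
    rx = np.array([a.coords for a in rec])
    lx = np.array([a.coords for a in lig])
    if np.isfinite(cutoff):
        d = np.sqrt(((rx[:, None, :] - lx[None, :, :]) ** 2).sum(axis=2))
        ii, jj = np.nonzero(d < cutoff)
        return [(rec[i], lig[j], float(d[i, j])) for i, j in zip(ii, jj)]
    d = np.sqrt(((rx[:, None, :] - lx[None, :, :]) ** 2).sum(axis=2))
    return [(rec[i], lig[j], float(d[i, j])) for i in range(len(rec)) for j in range(len(lig))]


# ---------------------------------------------------------------------------
# energy terms

def vdw_energy(pairs: Iterable[tuple[Atom, Atom, float]], params: ScoringParams) -> float:
    """Lennard-Jones 6-12 sum: Σ ε_ij[(σ_ij/r)¹² − 2(σ_ij/r)⁶].

    σ is the pair-minimum distance, so a pair at r = σ contributes exactly −ε.
    """
    total = 0.0
    for ai, aj, r in pairs:
        key = _sym((ai.atom_type, aj.atom_type))
        try:
            eps, sig = params.vdw_table[key]
        except KeyError:
            raise KeyError(f"no vdW parameters for atom-type pair {key}") from None
        sr6 = (sig / r) ** 6
        total += eps * (sr6 * sr6 - 2.0 * sr6)
    return total


def _is_charged_side_chain(atom: Atom) -> bool:
    from .structures_io import BACKBONE_ATOMS

    return atom.residue_name in CHARGED_RESIDUES and atom.name not in BACKBONE_ATOMS


def elec_energy(
    pairs: Iterable[tuple[Atom, Atom, float]],
    params: ScoringParams,
    charged_side_chains_only: bool = False,
) -> float:
    """Coulomb sum 332·q_i·q_j / r².

    With ``charged_side_chains_only`` the sum is restricted to pairs whose
    atoms both sit on Arg/Lys/Asp/Glu/His side chains (the long-range term B);
    the minimized-pose terms G/I use every charged atom.
    """
    total = 0.0
    for ai, aj, r in pairs:
        if ai.charge is None or aj.charge is None:
            raise ValueError(
                f"unassigned charge on atom {ai.serial if ai.charge is None else aj.serial};"
                " run assign_force_field first"
            )
        if charged_side_chains_only and not (
            _is_charged_side_chain(ai) and _is_charged_side_chain(aj)
        ):
            continue
        total += params.coulomb_constant * ai.charge * aj.charge / (r * r)
    return total


def ace_desolvation(pairs: Iterable[tuple[Atom, Atom, float]], params: ScoringParams) -> float:
    """ACE desolvation: Σ a_ij over cross-complex contact pairs."""
    total = 0.0
    for ai, aj, _r in pairs:
        ci, cj = _ace_class(ai), _ace_class(aj)
        if ci is None or cj is None:
            continue
        key = _sym((ci, cj))
        try:
            total += params.ace_table[key]
        except KeyError:
            raise KeyError(f"no ACE parameters for class pair {key}") from None
    return total


def zrank_score(b: float, c: float, e: float) -> float:
    """ZRank = ZRankElec + ZRankSolv + ZRankVdw."""
    return b + c + e


def zdock_score(psc: float, de: float, elec: float, params: ScoringParams) -> float:
    """Composite initial-docking score α·PSC + DE + β·ELEC."""
    return params.alpha * psc + de + params.beta * elec


def psc_proxy(pose: Pose, contact_shell: float = 5.0) -> float:
    """Cross-complex heavy-atom contact count within ``contact_shell`` Å.

    A documented stand-in for grid-based pairwise shape complementarity when
    no docking-program PSC is available; it approximates the geometric term
    as interface contact density and is never claimed equal to the grid score.
    """
    if contact_shell <= 0:
        raise ValueError("contact_shell must be positive")
    rec = [a for a in pose.receptor_atoms if a.element != "H"]
    lig = [a for a in pose.ligand_atoms if a.element != "H"]
    if not rec or not lig:
        return 0.0
    rx = np.array([a.coords for a in rec])
    lx = np.array([a.coords for a in lig])
    d2 = ((rx[:, None, :] - lx[None, :, :]) ** 2).sum(axis=2)
    return float(np.count_nonzero(d2 <= contact_shell * contact_shell))


# ---------------------------------------------------------------------------
# the feature vector

@dataclass
class FeatureVector:
    """The 11 energy features of one pose.

    Internal identities: ``zrank = zrank_elec + zrank_solv + zrank_vdw`` and
    ``e_rdock = e_sol + 0.9·e_elec2`` whenever all components were computed
    by this engine.
    """

    pose_id: str
    zdock: float
    zrank_elec: float
    zrank_solv: float
    zrank: float
    zrank_vdw: float
    e_vdw1: float
    e_elec1: float
    e_vdw2: float
    e_elec2: float
    e_sol: float
    e_rdock: float

    _ATTRS = [
        "zdock", "zrank_elec", "zrank_solv", "zrank", "zrank_vdw",
        "e_vdw1", "e_elec1", "e_vdw2", "e_elec2", "e_sol", "e_rdock",
    ]

    def as_series(self) -> pd.Series:
        vals = {LETTER_TO_NAME[c]: getattr(self, a) for c, a in zip(FEATURE_LETTERS, self._ATTRS)}
        return pd.Series({"pose_id": self.pose_id, **vals})

    def __getitem__(self, letter: str) -> float:
        return getattr(self, self._ATTRS[FEATURE_LETTERS.index(letter)])


def compute_features(
    docked: Pose,
    minimized1: Pose | None = None,
    minimized2: Pose | None = None,
    psc: float | None = None,
    params: ScoringParams | None = None,
) -> FeatureVector:
    """Compute all 11 features of a pose.

    ``minimized1``/``minimized2`` are the refinement-stage coordinate sets of
    the same complex (energy minimization itself is done upstream by the
    refinement program); when absent the docked coordinates stand in and a
    warning is logged.  ``psc`` is the docking program's shape-complementarity
    value; when absent :func:`psc_proxy` stands in.
    """
    if params is None:
        params = load_default_params()
    assign_force_field(docked, params)

    if minimized1 is None:
        logger.warning("pose %s: no 1st minimized coordinates; using docked pose for E_vdw1/E_elec1",
                       docked.pose_id)
        minimized1 = docked
    else:
        assign_force_field(minimized1, params)
    if minimized2 is None:
        logger.warning("pose %s: no 2nd minimized coordinates; using docked pose for E_vdw2/E_elec2/E_sol",
                       docked.pose_id)
        minimized2 = docked
    else:
        assign_force_field(minimized2, params)

    # docked-pose terms
    pairs_vdw = interface_pairs(docked, params.vdw_cutoff)
    pairs_ace = interface_pairs(docked, params.ace_cutoff)
    pairs_all = interface_pairs(docked, np.inf)
    b = elec_energy(pairs_all, params, charged_side_chains_only=True)
    c = ace_desolvation(pairs_ace, params)
    e = vdw_energy(pairs_vdw, params)
    d = zrank_score(b, c, e)

    if psc is None:
        psc = psc_proxy(docked, params.psc_contact_shell)
    elec_near = elec_energy(interface_pairs(docked, params.elec_min_cutoff), params)
    a = zdock_score(psc, c, elec_near, params)

    # minimized-pose terms
    f = vdw_energy(interface_pairs(minimized1, params.vdw_cutoff), params)
    g = elec_energy(interface_pairs(minimized1, params.elec_min_cutoff), params)
    h = vdw_energy(interface_pairs(minimized2, params.vdw_cutoff), params)
    i = elec_energy(interface_pairs(minimized2, params.elec_min_cutoff), params)
    j = ace_desolvation(interface_pairs(minimized2, params.ace_cutoff), params)
    k = j + params.elec_rdock_weight * i

    return FeatureVector(
        pose_id=docked.pose_id,
        zdock=a, zrank_elec=b, zrank_solv=c, zrank=d, zrank_vdw=e,
        e_vdw1=f, e_elec1=g, e_vdw2=h, e_elec2=i, e_sol=j, e_rdock=k,
    )
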