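"""Near-native labeling of docking poses against a reference complex.

A pose is near-native when its Cα-RMSD to the X-ray reference is ≤ 10 Å
(inclusive).  The default RMSD convention aligns the receptor (ankyrin) Cα
trace and measures the deviation over the ligand Cα trace — the ligand-RMSD
convention of docking assessment — with an all-Cα mode available.

The recognition-area filter (regKp) keeps poses whose ligand touches the
designated binding residues of the ankyrin second domain: at least
``min_contact_residues`` of the listed residues must have an atom within
``contact_cutoff`` Å (inclusive) of any ligand atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .structures_io import Pose, ca_map, residue_key
from .scoring import HYDROPHOBIC_RESIDUES

__all__ = [
    "NEAR_NATIVE_RMSD_CUTOFF",
    "PoseLabel",
    "RecognitionSpec",
    "superpose_kabsch",
    "ca_rmsd_vs_reference",
    "label_pose",
    "regkp_filter",
    "interface_composition",
]

NEAR_NATIVE_RMSD_CUTOFF = 10.0


@dataclass
class PoseLabel:
    pose_id: str
    ca_rmsd: float
    is_near_native: bool
    passes_regkp: bool
    complex_id: str

    def __post_init__(self) -> None:
        if self.ca_rmsd < 0:
            raise ValueError("ca_rmsd must be non-negative")
        if self.is_near_native != (self.ca_rmsd <= NEAR_NATIVE_RMSD_CUTOFF):
            raise ValueError("is_near_native inconsistent with ca_rmsd")


@dataclass
class RecognitionSpec:
    """The recognition residues on the ankyrin second domain.

    ``residues`` lists (chain_id, residue_seq) in author numbering — the
    identities are supplied per complex by the user, typically eight binding
    residues.
    """

    residues: list[tuple[str, int]]
    contact_cutoff: float = 5.0
    min_contact_residues: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("recognition residue list must be non-empty")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")


def superpose_kabsch(
    mobile: Sequence[Sequence[float]], reference: Sequence[Sequence[float]]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_after)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear) point geometry")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / n))
    return R, t, rmsd


def _matched_ca(pose: Pose, reference: Pose, part: Literal["receptor", "ligand"]):
    pm, rm = ca_map(pose, part), ca_map(reference, part)
    keys = sorted(set(pm) & set(rm))
    return (
        np.array([pm[k] for k in keys]).reshape(-1, 3),
        np.array([rm[k] for k in keys]).reshape(-1, 3),
    )


def ca_rmsd_vs_reference(
    pose: Pose,
    reference: Pose,
    align_on: Literal["receptor", "ligand"] = "receptor",
    measure: Literal["other", "all"] = "other",
) -> float:
    """Cα-RMSD of a pose against the reference complex.

    Residue correspondence is by (chain, residue number).  The pose is rigidly
    superposed on the reference over the ``align_on`` Cα set; the RMSD is then
    taken over the other partner's Cα atoms (``measure='other'``, the default
    ligand-deviation convention) or over all matched Cα atoms.
    """
    other: Literal["receptor", "ligand"] = "ligand" if align_on == "receptor" else "receptor"
    a_pose, a_ref = _matched_ca(pose, reference, align_on)
    if len(a_pose) < 3:
        raise ValueError(f"fewer than 3 matched CA atoms on the {align_on} alignment set")
    R, t, _ = superpose_kabsch(a_pose, a_ref)
    m_pose, m_ref = _matched_ca(pose, reference, other)
    if measure == "all":
        m_pose = np.vstack([a_pose, m_pose])
        m_ref = np.vstack([a_ref, m_ref])
    if len(m_pose) == 0:
        raise ValueError("no matched CA atoms to measure over")
    moved = m_pose @ R.T + t
    return float(np.sqrt(((moved - m_ref) ** 2).sum() / len(m_pose)))


def label_pose(ca_rmsd: float, cutoff: float = NEAR_NATIVE_RMSD_CUTOFF) -> bool:
    """True (near-native) iff ``ca_rmsd`` ≤ cutoff; the boundary is inclusive."""
    if ca_rmsd < 0:
        raise ValueError("ca_rmsd must be non-negative")
    return ca_rmsd <= cutoff


def regkp_filter(pose: Pose, spec: RecognitionSpec) -> bool:
    """Recognition-area filter: does the ligand contact the listed residues?

    True iff at least ``spec.min_contact_residues`` of the recognition
    residues have any atom within ``spec.contact_cutoff`` Å (inclusive) of
    any ligand atom.  A listed residue absent from the receptor is an error.
    """
    by_res: dict[tuple[str, int], list[np.ndarray]] = {}
    for a in pose.receptor_atoms:
        by_res.setdefault((a.chain_id, a.residue_seq), []).append(a.coords)
    lig = np.array([a.coords for a in pose.ligand_atoms])
    n_contact = 0
    for res in spec.residues:
        if tuple(res) not in by_res:
            raise ValueError(f"recognition residue {res} not found in receptor")
        coords = np.array(by_res[tuple(res)])
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= spec.contact_cutoff**2:
            n_contact += 1
    return n_contact >= spec.min_contact_residues


def interface_composition(
    pose: Pose,
    cutoff: float = 5.0,
    variable_residues: Iterable[tuple[str, int]] = (),
    hydrophobic_set: set[str] | None = None,
) -> tuple[float, float, dict[str, float]]:
    """Residue-level composition of the binding interface.

    The interface is every residue with any cross-complex atom distance
    ≤ ``cutoff``.  Returns ``(pct_variable, pct_hydrophobic, pair_fractions)``
    where the percentages are over receptor interface residues (the ankyrin
    interaction area) and ``pair_fractions`` classifies residue contact pairs
    as hydrophobic–hydrophobic / hydrophobic–polar / polar–polar, in percent
    summing to 100.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    hp = HYDROPHOBIC_RESIDUES if hydrophobic_set is None else hydrophobic_set
    variable = {tuple(v) for v in variable_residues}

    def group(atoms):
        out: dict[tuple[str, int, str], tuple[str, np.ndarray]] = {}
        for a in atoms:
            key = residue_key(a)
            out.setdefault(key, (a.residue_name, []))[1].append(a.coords)  # type: ignore[index]
        return {k: (name, np.array(c)) for k, (name, c) in out.items()}

    rec = group(pose.receptor_atoms)
    lig = group(pose.ligand_atoms)
    rec_iface: set = set()
    lig_iface: set = set()
    contact_pairs: list[tuple[str, str]] = []
    for rk, (rname, rc) in rec.items():
        for lk, (lname, lc) in lig.items():
            d2 = ((rc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                rec_iface.add(rk)
                lig_iface.add(lk)
                contact_pairs.append((rname, lname))
    if not rec_iface:
        raise ValueError("empty interface at this cutoff")

    n_rec = len(rec_iface)
    n_var = sum(1 for (ch, seq, _ic) in rec_iface if (ch, seq) in variable)
    n_hyd = sum(1 for k in rec_iface if rec[k][0] in hp)
    counts = {"hh": 0, "hp": 0, "pp": 0}
    for rname, lname in contact_pairs:
        nh = (rname in hp) + (lname in hp)
        counts["hh" if nh == 2 else "hp" if nh == 1 else "pp"] += 1
    total = len(contact_pairs)
    fractions = {k: 100.0 * v / total for k, v in counts.items()}
    return 100.0 * n_var / n_rec, 100.0 * n_hyd / n_rec, fractions
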