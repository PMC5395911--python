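"""Minimal PDB coordinate I/O for docking-pose scoring.

Poses are pairs of chain sets: the ankyrin receptor and its docked target
ligand.  Coordinates and author residue numbering are kept verbatim from the
file — recognition-residue lists reference author numbering, so nothing is
renumbered.  Only the first MODEL of multi-model files is read, the first
altloc of alternate conformers is kept, and HETATM waters are ignored.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Pose",
    "read_pdb",
    "write_pdb",
    "ca_coordinates",
    "residue_key",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    """One ATOM record.

    ``charge`` and ``atom_type`` are force-field annotations assigned later by
    the scoring module; they are ``None`` straight after parsing.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    icode: str = ""
    charge: float | None = None
    atom_type: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates")


def residue_key(atom: Atom) -> tuple[str, int, str]:
    """Sort/identity key of an atom's residue: (chain, seq, insertion code)."""
    return (atom.chain_id, atom.residue_seq, atom.icode)


@dataclass
class Pose:
    """A docked receptor–ligand complex.

    ``source_stage`` records which coordinate set this is: the raw docked
    pose, or the first/second energy-minimized refinement of it.
    """

    pose_id: str
    receptor_atoms: list[Atom]
    ligand_atoms: list[Atom]
    source_stage: Literal["docked", "minimized1", "minimized2"] = "docked"

    def __post_init__(self) -> None:
        if not self.receptor_atoms or not self.ligand_atoms:
            raise ValueError(f"pose {self.pose_id}: receptor and ligand must be non-empty")
        rc = {a.chain_id for a in self.receptor_atoms}
        lc = {a.chain_id for a in self.ligand_atoms}
        if rc & lc:
            raise ValueError(f"pose {self.pose_id}: chain sets overlap: {sorted(rc & lc)}")

    @property
    def receptor_chains(self) -> set[str]:
        return {a.chain_id for a in self.receptor_atoms}

    @property
    def ligand_chains(self) -> set[str]:
        return {a.chain_id for a in self.ligand_atoms}

    def copy(self) -> "Pose":
        return copy.deepcopy(self)

    def translated_ligand(self, shift: Sequence[float], pose_id: str | None = None) -> "Pose":
        """Return a copy with the ligand rigidly translated by ``shift`` (Å)."""
        new = self.copy()
        vec = np.asarray(shift, dtype=float)
        for a in new.ligand_atoms:
            a.coords = a.coords + vec
        if pose_id is not None:
            new.pose_id = pose_id
        return new


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        residue_name = line[17:20].strip()
        chain_id = line[21]
        residue_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        # Derive from the atom name: PDB right-justifies single-letter
        # elements into column 14, so the first alphabetic char works for
        # standard amino-acid atoms.
        element = next((c for c in name if c.isalpha()), "C")
        if name[:1].isdigit() or name.startswith("H"):
            element = "H" if any(c == "H" for c in name) else element
    atom = Atom(
        serial=serial,
        name=name,
        element=element.upper(),
        residue_name=residue_name,
        chain_id=chain_id,
        residue_seq=residue_seq,
        coords=np.array([x, y, z]),
        icode=icode,
    )
    atom._altloc = altloc  # type: ignore[attr-defined] # transient, used for first-altloc filtering
    return atom


def read_pdb(
    path: str | Path,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    pose_id: str | None = None,
    source_stage: Literal["docked", "minimized1", "minimized2"] = "docked",
) -> Pose:
    """Read a PDB file and partition its atoms into receptor and ligand.

    Parameters
    ----------
    path
        PDB file with ATOM records for every requested chain.
    receptor_chains, ligand_chains
        Disjoint chain-id sets; the receptor is the ankyrin.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If a requested chain has no atoms, or an ATOM line is malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    if receptor_chains & ligand_chains:
        raise ValueError("receptor and ligand chain sets must be disjoint")
    wanted = receptor_chains | ligand_chains

    receptor: list[Atom] = []
    ligand: list[Atom] = []
    seen_altloc: set[tuple[str, int, str, str]] = set()
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                in_first_model = False
            if not in_first_model:
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            atom = _parse_atom_line(line, lineno)
            if rec == "HETATM" and atom.residue_name in _WATER_NAMES:
                continue
            if atom.chain_id not in wanted:
                continue
            altloc = getattr(atom, "_altloc", " ")
            if altloc not in (" ", ""):
                key = (atom.chain_id, atom.residue_seq, atom.icode, atom.name)
                if key in seen_altloc:
                    continue  # keep first altloc only
                seen_altloc.add(key)
            (receptor if atom.chain_id in receptor_chains else ligand).append(atom)

    found = {a.chain_id for a in receptor} | {a.chain_id for a in ligand}
    missing = wanted - found
    if missing:
        raise ValueError(f"{path}: requested chain(s) not found: {sorted(missing)}")
    return Pose(
        pose_id=pose_id if pose_id is not None else path.stem,
        receptor_atoms=receptor,
        ligand_atoms=ligand,
        source_stage=source_stage,
    )


def write_pdb(pose: Pose, path: str | Path) -> None:
    """Write a pose back to PDB format (ATOM records only, 3-decimal coords)."""
    with open(path, "w") as fh:
        for atom in list(pose.receptor_atoms) + list(pose.ligand_atoms):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<3s} {ch}{seq:>4d}{icode:<1s}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=atom.serial,
                    name=name,
                    res=atom.residue_name,
                    ch=atom.chain_id,
                    seq=atom.residue_seq,
                    icode=atom.icode or "",
                    x=atom.coords[0],
                    y=atom.coords[1],
                    z=atom.coords[2],
                    occ=1.0,
                    b=0.0,
                    el=atom.element,
                )
            )
        fh.write("END\n")


def ca_coordinates(
    pose: Pose, part: Literal["receptor", "ligand", "both"] = "both"
) -> list[np.ndarray]:
    """Ordered Cα coordinates, one per residue that has an atom named CA.

    Ordering is by (chain, residue number, insertion code), independent of the
    record order in the source file.  Residues without a CA atom are skipped.
    """
    if part == "receptor":
        atoms = pose.receptor_atoms
    elif part == "ligand":
        atoms = pose.ligand_atoms
    elif part == "both":
        atoms = list(pose.receptor_atoms) + list(pose.ligand_atoms)
    else:
        raise ValueError(f"unknown part {part!r}")
    cas: dict[tuple[str, int, str], np.ndarray] = {}
    for a in atoms:
        if a.name == "CA" and residue_key(a) not in cas:
            cas[residue_key(a)] = a.coords
    if not cas:
        raise ValueError(f"pose {pose.pose_id}: no CA atoms in {part}")
    return [cas[k] for k in sorted(cas)]


def ca_map(pose: Pose, part: Literal["receptor", "ligand"]) -> dict[tuple[str, int, str], np.ndarray]:
    """Residue-keyed Cα coordinates, for correspondence matching between poses."""
    atoms = pose.receptor_atoms if part == "receptor" else pose.ligand_atoms
    out: dict[tuple[str, int, str], np.ndarray] = {}
    for a in atoms:
        if a.name == "CA" and residue_key(a) not in out:
            out[residue_key(a)] = a.coords
    return out
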