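import numpy as np
import pytest

from ankplex.scoring import load_default_params
from ankplex.structures_io import Atom, Pose
from ankplex.synthetic_data import generate_toy_complex


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   1.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   2.400   0.100  1.00  0.00           C
ATOM      4  N   GLY B   5       1.000   5.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY B   5       2.458   5.000   0.000  1.00  0.00           C
ATOM      6  C   GLY B   5       3.000   6.400   0.100  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB ASER A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB BSER A   1       1.200   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY B   2       4.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture
def toy_complex():
    return generate_toy_complex(n_res_receptor=10, n_res_ligand=8, displacement=7.0, seed=3)


def make_atom(serial, coords, name="CA", element="C", residue_name="ALA",
              chain_id="A", residue_seq=1, charge=None, atom_type=None):
    a = Atom(serial=serial, name=name, element=element, residue_name=residue_name,
             chain_id=chain_id, residue_seq=residue_seq, coords=np.asarray(coords, float))
    a.charge = charge
    a.atom_type = atom_type if atom_type is not None else element
    return a


def make_pair_pose(r, pose_id="pair"):
    """Two single-atom chains separated by distance r along x."""
    rec = [make_atom(1, [0, 0, 0], chain_id="A")]
    lig = [make_atom(2, [r, 0, 0], chain_id="B")]
    return Pose(pose_id=pose_id, receptor_atoms=rec, ligand_atoms=lig)
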