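import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ankplex.labeling import (
    RecognitionSpec,
    ca_rmsd_vs_reference,
    interface_composition,
    label_pose,
    regkp_filter,
    superpose_kabsch,
)
from ankplex.structures_io import Pose
from ankplex.synthetic_data import generate_toy_complex

from conftest import make_atom


def quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's quaternion method for optimal RMSD."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (P0**2).sum() + (Q0**2).sum()
    return np.sqrt(max(e0 - 2 * lam, 0.0) / len(P))


class TestSuperposeKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        R, t, rmsd = superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        R, t, rmsd = superpose_kabsch(pts + [1.0, -2.0, 3.0], pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        # reflection of the point set still yields a proper rotation
        R, _, _ = superpose_kabsch(pts * [-1, 1, 1], pts)
        assert np.linalg.det(R) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(scale=5.0, size=(10, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        mobile = (ref @ rot.T + rng.normal(scale=0.5, size=(10, 3))) + rng.normal(size=3)
        _, _, rmsd = superpose_kabsch(mobile, ref)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(mobile, ref), abs=1e-6)

    def test_rejects_degenerate_inputs(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError):
            superpose_kabsch(line, line)
        with pytest.raises(ValueError):
            superpose_kabsch(np.zeros((4, 3)), np.zeros((5, 3)))


class TestCaRmsd:
    def test_pose_equals_reference(self):
        ref, _ = generate_toy_complex(8, 6, displacement=0.0, seed=0)
        assert ca_rmsd_vs_reference(ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_ligand_shift(self):
        ref, decoy = generate_toy_complex(8, 6, displacement=7.0, seed=0)
        assert ca_rmsd_vs_reference(decoy, ref) == pytest.approx(7.0, abs=1e-9)

    def test_matches_two_step_oracle(self):
        """Receptor-align + ligand-RMSD agrees with an independent computation."""
        ref, decoy = generate_toy_complex(10, 8, displacement=4.0, seed=5)
        # scramble: rotate the whole decoy rigidly; RMSD must be unchanged
        rot = Rotation.from_euler("xyz", [0.3, -0.5, 1.1]).as_matrix()
        shift = np.array([4.0, -3.0, 9.0])
        moved = decoy.copy()
        for a in moved.receptor_atoms + moved.ligand_atoms:
            a.coords = rot @ a.coords + shift
        from ankplex.structures_io import ca_map

        pm, rm = ca_map(moved, "receptor"), ca_map(ref, "receptor")
        keys = sorted(set(pm) & set(rm))
        R, t, _ = superpose_kabsch([pm[k] for k in keys], [rm[k] for k in keys])
        pl, rl = ca_map(moved, "ligand"), ca_map(ref, "ligand")
        lkeys = sorted(set(pl) & set(rl))
        moved_lig = np.array([pl[k] for k in lkeys]) @ R.T + t
        expected = np.sqrt(((moved_lig - np.array([rl[k] for k in lkeys])) ** 2).sum() / len(lkeys))
        assert ca_rmsd_vs_reference(moved, ref) == pytest.approx(expected, abs=1e-9)
        assert ca_rmsd_vs_reference(moved, ref) == pytest.approx(4.0, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self):
        ref, decoy = generate_toy_complex(8, 6, displacement=6.0, seed=7)
        base = ca_rmsd_vs_reference(decoy, ref)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        for pose in (ref, decoy):
            for a in pose.receptor_atoms + pose.ligand_atoms:
                a.coords = rot @ a.coords + np.array([1.0, 2.0, 3.0])
        assert ca_rmsd_vs_reference(decoy, ref) == pytest.approx(base, abs=1e-9)

    def test_too_few_matched_ca_raises(self):
        rec = [make_atom(i, [3.8 * i, 0, 0], name="CA", residue_seq=i) for i in range(1, 3)]
        lig = [make_atom(10 + i, [3.8 * i, 5, 0], name="CA", chain_id="B", residue_seq=i)
               for i in range(1, 5)]
        small = Pose(pose_id="s", receptor_atoms=rec, ligand_atoms=lig)
        with pytest.raises(ValueError, match="3 matched"):
            ca_rmsd_vs_reference(small, small)


class TestLabelPose:
    @pytest.mark.parametrize(
        "rmsd, expected",
        [(10.0, True), (10.000001, False), (0.0, True), (9.99, True), (25.0, False)],
    )
    def test_inclusive_threshold(self, rmsd, expected):
        assert label_pose(rmsd) is expected

    def test_monotone(self):
        rng = np.random.default_rng(0)
        vals = np.sort(rng.uniform(0, 20, 50))
        labels = [label_pose(v) for v in vals]
        # once a pose is non-near-native, no larger RMSD is near-native
        assert labels == sorted(labels, reverse=True)

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            label_pose(-0.1)


class TestRegkpFilter:
    def test_contact_passes(self):
        ref, _ = generate_toy_complex(8, 6, seed=0)
        spec = RecognitionSpec(residues=[("A", 2), ("A", 3), ("A", 4)])
        assert regkp_filter(ref, spec) is True

    def test_displaced_ligand_fails(self):
        _, decoy = generate_toy_complex(8, 6, displacement=50.0, seed=0)
        spec = RecognitionSpec(residues=[("A", 2), ("A", 3)])
        assert regkp_filter(decoy, spec) is False

    def test_boundary_inclusive_vs_brute_force(self):
        rec = [make_atom(1, [0, 0, 0], name="CA", residue_seq=1)]
        lig = [make_atom(2, [5.0, 0, 0], name="CA", chain_id="B", residue_seq=1)]
        pose = Pose(pose_id="b", receptor_atoms=rec, ligand_atoms=lig)
        assert regkp_filter(pose, RecognitionSpec(residues=[("A", 1)], contact_cutoff=5.0))
        lig[0].coords = np.array([5.001, 0, 0])
        pose2 = Pose(pose_id="b2", receptor_atoms=rec, ligand_atoms=lig)
        assert not regkp_filter(pose2, RecognitionSpec(residues=[("A", 1)], contact_cutoff=5.0))

    def test_missing_residue_named(self):
        ref, _ = generate_toy_complex(8, 6, seed=0)
        with pytest.raises(ValueError, match="99"):
            regkp_filter(ref, RecognitionSpec(residues=[("A", 99)]))

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        ref, _ = generate_toy_complex(8, 6, seed=1)
        spec = RecognitionSpec(residues=[("A", 3), ("A", 5)])
        before = regkp_filter(ref, spec)
        rot = Rotation.from_euler("xyz", [0.4, 1.2, -0.3]).as_matrix()
        for a in ref.receptor_atoms + ref.ligand_atoms:
            a.coords = rot @ a.coords + np.array([10.0, -5.0, 2.0])
        assert regkp_filter(ref, spec) == before


class TestInterfaceComposition:
    def _two_residue_pose(self, rec_names, lig_names):
        rec, lig = [], []
        for i, rn in enumerate(rec_names):
            rec.append(make_atom(i + 1, [4.0 * i, 0, 0], residue_name=rn, residue_seq=i + 1))
        for i, ln in enumerate(lig_names):
            lig.append(make_atom(50 + i, [4.0 * i, 4.0, 0], residue_name=ln,
                                 chain_id="B", residue_seq=i + 1))
        return Pose(pose_id="c", receptor_atoms=rec, ligand_atoms=lig)

    def test_all_hydrophobic_interface(self):
        pose = self._two_residue_pose(["LEU", "VAL"], ["ILE", "ALA"])
        _, pct_h, fr = interface_composition(pose, cutoff=5.0)
        assert pct_h == 100.0
        assert fr["hh"] == 100.0 and fr["hp"] == 0.0 and fr["pp"] == 0.0

    def test_variable_residue_percentage(self):
        pose = self._two_residue_pose(["LEU", "SER", "VAL", "THR"], ["GLY"] * 4)
        pct_var, _, _ = interface_composition(
            pose, cutoff=5.0, variable_residues=[("A", 1), ("A", 2)]
        )
        assert pct_var == pytest.approx(50.0)

    def test_mixed_fractions_match_hand_count(self):
        # contacts are residue i of A with residue i of B only (4.0 Å apart,
        # neighbours at >5.5 Å): LEU-SER (hp), SER-SER (pp), VAL-ILE (hh)
        pose = self._two_residue_pose(["LEU", "SER", "VAL"], ["SER", "SER", "ILE"])
        _, _, fr = interface_composition(pose, cutoff=5.0)
        assert fr["hh"] == pytest.approx(100 / 3)
        assert fr["hp"] == pytest.approx(100 / 3)
        assert fr["pp"] == pytest.approx(100 / 3)

    def test_fractions_sum_to_100(self, toy_complex):
        ref, _ = toy_complex
        _, _, fr = interface_composition(ref, cutoff=6.0)
        assert sum(fr.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_interface_raises(self):
        pose = self._two_residue_pose(["LEU"], ["LEU"])
        for a in pose.ligand_atoms:
            a.coords = a.coords + np.array([0.0, 100.0, 0.0])
        with pytest.raises(ValueError, match="empty interface"):
            interface_composition(pose, cutoff=5.0)
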