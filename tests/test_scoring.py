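import numpy as np
import pytest

from ankplex.scoring import (
    FEATURE_NAMES,
    ScoringParams,
    ace_desolvation,
    assign_force_field,
    compute_features,
    elec_energy,
    interface_pairs,
    load_default_params,
    psc_proxy,
    vdw_energy,
    zdock_score,
    zrank_score,
)
from ankplex.structures_io import Pose
from ankplex.synthetic_data import generate_toy_complex

from conftest import make_atom, make_pair_pose


def random_two_chain_pose(n_each=25, seed=0, spread=8.0):
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S"]
    rec = [
        make_atom(i + 1, rng.uniform(0, spread, 3), name="CA",
                  element=elements[i % 4], chain_id="A", residue_seq=i + 1,
                  charge=float(rng.uniform(-0.5, 0.5)))
        for i in range(n_each)
    ]
    lig = [
        make_atom(100 + i, rng.uniform(0, spread, 3) + [spread / 2, 0, 0], name="CA",
                  element=elements[(i + 1) % 4], chain_id="B", residue_seq=i + 1,
                  charge=float(rng.uniform(-0.5, 0.5)))
        for i in range(n_each)
    ]
    return Pose(pose_id="rand", receptor_atoms=rec, ligand_atoms=lig)


class TestInterfacePairs:
    def test_pair_within_cutoff(self):
        pose = make_pair_pose(3.0)
        assert len(interface_pairs(pose, 5.0)) == 1

    def test_cutoff_boundary_is_strict(self):
        pose = make_pair_pose(5.0)
        assert interface_pairs(pose, 5.0) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        pose = random_two_chain_pose(seed=seed)
        got = {(a.serial, b.serial) for a, b, _ in interface_pairs(pose, 5.0)}
        expected = set()
        for a in pose.receptor_atoms:
            for b in pose.ligand_atoms:
                if np.linalg.norm(a.coords - b.coords) < 5.0:
                    expected.add((a.serial, b.serial))
        assert got == expected

    def test_no_intra_chain_pairs(self):
        pose = random_two_chain_pose(seed=3)
        for a, b, _ in interface_pairs(pose, 50.0):
            assert a.chain_id == "A" and b.chain_id == "B"


class TestVdwEnergy:
    def test_minimum_at_sigma(self, params):
        pose = make_pair_pose(4.0)  # C-C sigma is 4.0 in the reduced table
        pairs = interface_pairs(pose, 5.0)
        eps = params.vdw_table[("C", "C")][0]
        assert vdw_energy(pairs, params) == pytest.approx(-eps)

    def test_direct_evaluation(self):
        params = ScoringParams(vdw_table={("C", "C"): (0.1, 3.0)})
        pose = make_pair_pose(4.0)
        pairs = interface_pairs(pose, 5.0)
        expected = 0.1 * (0.75**12 - 2 * 0.75**6)
        assert vdw_energy(pairs, params) == pytest.approx(expected)

    def test_empty_pairs_zero(self, params):
        assert vdw_energy([], params) == 0.0

    def test_missing_type_pair_named(self):
        params = ScoringParams(vdw_table={("C", "C"): (0.1, 3.0)})
        a = make_atom(1, [0, 0, 0], atom_type="X")
        b = make_atom(2, [3, 0, 0], chain_id="B", atom_type="C")
        with pytest.raises(KeyError, match="X"):
            vdw_energy([(a, b, 3.0)], params)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_brute_force_sum(self, seed, params):
        pose = random_two_chain_pose(seed=seed)
        pairs = interface_pairs(pose, 5.0)
        expected = 0.0
        for a, b, r in pairs:
            eps, sig = params.vdw_table[tuple(sorted((a.atom_type, b.atom_type)))]
            expected += eps * ((sig / r) ** 12 - 2 * (sig / r) ** 6)
        assert vdw_energy(pairs, params) == pytest.approx(expected)


class TestElecEnergy:
    def test_unit_charges_at_one_angstrom(self, params):
        a = make_atom(1, [0, 0, 0], charge=1.0)
        b = make_atom(2, [1, 0, 0], chain_id="B", charge=1.0)
        assert elec_energy([(a, b, 1.0)], params) == pytest.approx(332.0)

    def test_opposite_charges(self, params):
        a = make_atom(1, [0, 0, 0], charge=1.0)
        b = make_atom(2, [2, 0, 0], chain_id="B", charge=-1.0)
        assert elec_energy([(a, b, 2.0)], params) == pytest.approx(-83.0)

    def test_all_neutral_with_flag(self, params):
        pose = random_two_chain_pose(seed=4)
        for a in pose.receptor_atoms + pose.ligand_atoms:
            a.charge = 0.0
        pairs = interface_pairs(pose, 12.0)
        assert elec_energy(pairs, params, charged_side_chains_only=True) == 0.0

    def test_unassigned_charge_raises(self, params):
        a = make_atom(1, [0, 0, 0], charge=None)
        b = make_atom(2, [1, 0, 0], chain_id="B", charge=1.0)
        with pytest.raises(ValueError, match="charge"):
            elec_energy([(a, b, 1.0)], params)

    def test_charged_side_chain_filter(self, params):
        # Lys NZ vs Asp OD1 pair counts; backbone pair does not
        nz = make_atom(1, [0, 0, 0], name="NZ", element="N", residue_name="LYS", charge=1.0)
        od = make_atom(2, [2, 0, 0], name="OD1", element="O", residue_name="ASP",
                       chain_id="B", charge=-0.57)
        bb = make_atom(3, [0, 3, 0], name="N", element="N", residue_name="LYS", charge=-0.35)
        bb2 = make_atom(4, [2, 3, 0], name="N", element="N", residue_name="ASP",
                        chain_id="B", charge=-0.35)
        pairs = [(nz, od, 2.0), (bb, bb2, 2.0), (nz, bb2, np.sqrt(13.0))]
        got = elec_energy(pairs, params, charged_side_chains_only=True)
        assert got == pytest.approx(332 * 1.0 * -0.57 / 4.0)


class TestAceDesolvation:
    def test_single_pair(self):
        params = ScoringParams(ace_table={("CP", "CP"): -1.3})
        a = make_atom(1, [0, 0, 0], residue_name="SER")
        b = make_atom(2, [3, 0, 0], chain_id="B", residue_name="SER")
        assert ace_desolvation([(a, b, 3.0)], params) == pytest.approx(-1.3)

    def test_empty_interface_zero(self, params):
        assert ace_desolvation([], params) == 0.0

    def test_mixed_sign_sum_matches_hand_count(self, params):
        pose = random_two_chain_pose(seed=5)
        pairs = interface_pairs(pose, 6.0)
        from ankplex.scoring import _ace_class

        expected = sum(
            params.ace_table[tuple(sorted((_ace_class(a), _ace_class(b))))]
            for a, b, _ in pairs
        )
        assert ace_desolvation(pairs, params) == pytest.approx(expected)

    def test_missing_class_raises(self):
        params = ScoringParams(ace_table={})
        a = make_atom(1, [0, 0, 0], residue_name="LEU")
        b = make_atom(2, [3, 0, 0], chain_id="B", residue_name="LEU")
        with pytest.raises(KeyError):
            ace_desolvation([(a, b, 3.0)], params)


@pytest.mark.parametrize(
    "b, c, e, expected",
    [
        (8.22, 3.66, -65.91, -54.03),
        (0.0, 0.0, 0.0, 0.0),
        (1.0, 2.0, 3.0, 6.0),
    ],
)
def test_zrank_score(b, c, e, expected):
    assert zrank_score(b, c, e) == pytest.approx(expected)


class TestZdockScore:
    def test_default_weights(self, params):
        assert zdock_score(100, -5, -20, params) == pytest.approx(1 - 5 - 1.2)

    def test_zero(self, params):
        assert zdock_score(0, 0, 0, params) == 0.0

    def test_random_triples_match_direct_formula(self, params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            psc, de, elec = rng.uniform(-100, 100, 3)
            assert zdock_score(psc, de, elec, params) == pytest.approx(
                params.alpha * psc + de + params.beta * elec
            )


class TestPscProxy:
    def test_far_apart_chains_zero(self):
        pose = make_pair_pose(100.0)
        assert psc_proxy(pose, 4.0) == 0.0

    def test_single_contact(self):
        pose = make_pair_pose(3.0)
        assert psc_proxy(pose, 4.0) == 1.0

    def test_matches_brute_force_count(self):
        pose = random_two_chain_pose(seed=6)
        expected = sum(
            np.linalg.norm(a.coords - b.coords) <= 5.0
            for a in pose.receptor_atoms
            for b in pose.ligand_atoms
        )
        assert psc_proxy(pose, 5.0) == expected


class TestComputeFeatures:
    def test_internal_identities(self, params):
        ref, _ = generate_toy_complex(8, 6, seed=1)
        fv = compute_features(ref, params=params)
        assert fv.zrank == pytest.approx(fv.zrank_elec + fv.zrank_solv + fv.zrank_vdw, abs=1e-6)
        assert fv.e_rdock == pytest.approx(fv.e_sol + 0.9 * fv.e_elec2, abs=1e-6)

    def test_componentwise_equivalence(self, params):
        ref, _ = generate_toy_complex(8, 6, seed=2)
        fv = compute_features(ref, params=params)
        assign_force_field(ref, params)
        assert fv.zrank_vdw == pytest.approx(
            vdw_energy(interface_pairs(ref, params.vdw_cutoff), params)
        )
        assert fv.zrank_solv == pytest.approx(
            ace_desolvation(interface_pairs(ref, params.ace_cutoff), params)
        )
        assert fv.zrank_elec == pytest.approx(
            elec_energy(interface_pairs(ref, np.inf), params, charged_side_chains_only=True)
        )

    def test_absent_minimized_uses_docked_with_warning(self, params, caplog):
        ref, _ = generate_toy_complex(8, 6, seed=3)
        import logging

        with caplog.at_level(logging.WARNING, logger="ankplex.scoring"):
            fv = compute_features(ref, params=params)
        assert "minimized" in caplog.text
        assert fv.e_vdw1 == pytest.approx(fv.zrank_vdw)

    def test_minimized_poses_drive_f_through_k(self, params):
        ref, decoy = generate_toy_complex(8, 6, displacement=1.0, seed=4)
        fv = compute_features(ref.copy(), minimized1=decoy.copy(), minimized2=decoy.copy(),
                              params=params)
        fv_dec = compute_features(decoy.copy(), params=params)
        assert fv.e_vdw1 == pytest.approx(fv_dec.zrank_vdw)
        assert fv.e_sol == pytest.approx(fv_dec.e_sol)


class TestEnergyProperties:
    def test_pair_symmetry(self, params):
        """Energies are symmetric in the receptor/ligand roles of a pair."""
        a = make_atom(1, [0, 0, 0], element="N", charge=0.4, residue_name="LEU")
        b = make_atom(2, [3, 0, 0], chain_id="B", element="O", charge=-0.3,
                      residue_name="SER")
        for f in (vdw_energy, elec_energy, ace_desolvation):
            assert f([(a, b, 3.0)], params) == pytest.approx(f([(b, a, 3.0)], params))

    def test_additivity_over_disjoint_interfaces(self, params):
        pose = random_two_chain_pose(seed=8)
        pairs = interface_pairs(pose, 6.0)
        half1, half2 = pairs[: len(pairs) // 2], pairs[len(pairs) // 2:]
        for f in (vdw_energy, elec_energy, ace_desolvation):
            assert f(pairs, params) == pytest.approx(f(half1, params) + f(half2, params))

    def test_vdw_vanishes_at_long_range(self, params):
        far = [(make_atom(1, [0, 0, 0]), make_atom(2, [1e5, 0, 0], chain_id="B"), 1e5)]
        assert abs(vdw_energy(far, params)) < 1e-20
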