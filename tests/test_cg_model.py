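"""Topology building and the coarse-grained energy function."""

import numpy as np
import pandas as pd
import pytest

import biotite.structure as bst

from ssbwrap.cgtop import (
    KIND_B,
    KIND_P,
    BeadTopology,
    assign_charge_state,
    build_protein_topology,
    build_ssdna_topology,
    interface_reference_distances,
    merge_topologies,
)
from ssbwrap.energy import (
    SimulationParams,
    debye_length,
    electrostatic_energy,
    interface_contact_energy,
    total_energy_and_forces,
)
from ssbwrap.constants import COULOMB_KCAL_A


def _chain(coords, resnames=None, chain="A"):
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([chain] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(resnames or ["GLY"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


class TestProteinTopology:
    def test_extended_chain_counts(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = 3.8 * np.arange(10)
        top = build_protein_topology(_chain(coords))
        assert len(top.bonds) == 9
        assert len(top.angles) == 8
        assert len(top.dihedrals) == 7
        assert len(top.pairs) == 0  # extended geometry has no contacts

    def test_contact_count_matches_brute_force(self, toy):
        top = toy.build_topology()
        prot = np.flatnonzero(top.molecule == 0)
        pos = top.positions[prot]
        n = pos.shape[0]
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                same = top.subunit[i] == top.subunit[j]
                if same and abs(i - j) < 4:
                    continue
                if np.linalg.norm(pos[i] - pos[j]) <= 6.5:
                    count += 1
        protein_pairs = top.pairs[
            (top.molecule[top.pairs[:, 0]] == 0) & (top.molecule[top.pairs[:, 1]] == 0)
        ]
        assert len(protein_pairs) == count

    def test_chain_break_skips_bond_with_warning(self):
        coords = np.zeros((5, 3))
        coords[:, 0] = [0.0, 3.8, 7.6, 30.0, 33.8]
        with pytest.warns(UserWarning, match="chain break"):
            top = build_protein_topology(_chain(coords))
        assert len(top.bonds) == 3

    def test_default_residue_charges(self):
        coords = np.zeros((4, 3))
        coords[:, 0] = 3.8 * np.arange(4)
        top = build_protein_topology(
            _chain(coords, ["LYS", "GLU", "HIS", "GLY"])
        )
        assert top.charges.tolist() == [1.0, -1.0, 0.0, 0.0]

    def test_structure_without_ca_rejected(self):
        arr = _chain(np.zeros((2, 3)))
        arr.atom_name = np.array(["CB", "CB"])
        with pytest.raises(ValueError, match="C-alpha"):
            build_protein_topology(arr)


class TestSsdnaTopology:
    @pytest.mark.parametrize(
        "seq,n_beads,n_bonds,n_stack",
        [("TT", 5, 4, 1), ("T" * 19, 56, 55, 18), ("T" * 70, 209, 208, 69)],
    )
    def test_bead_and_bond_counts(self, seq, n_beads, n_bonds, n_stack):
        top = build_ssdna_topology(seq)
        assert top.n_beads == n_beads
        assert len(top.bonds) == n_bonds
        stacks = top.pairs
        assert len(stacks) == n_stack

    def test_phosphate_charges(self):
        top = build_ssdna_topology("T" * 19)
        assert (top.charges != 0).sum() == 18
        assert np.all(top.charges[top.kinds == KIND_P] == -0.6)

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_ssdna_topology("TXT")


class TestChargeState:
    def _toy_topology(self):
        coords = np.zeros((4, 3))
        coords[:, 0] = 3.8 * np.arange(4)
        return build_protein_topology(_chain(coords, ["ARG", "GLY", "GLY", "GLY"]))

    def test_identical_states_give_identical_charges(self):
        top = self._toy_topology()
        ov = pd.DataFrame(
            [(0, 1, s, 0.5) for s in ("unbridged", "bridged")],
            columns=["subunit", "residue_index", "state", "charge_e"],
        )
        a = assign_charge_state(top, "unbridged", ov)
        b = assign_charge_state(top, "bridged", ov)
        np.testing.assert_array_equal(a.charges, b.charges)

    def test_bridged_pocket_increment_arithmetic(self, toy):
        # +0.2e added to 8 pocket residues per subunit shifts the total by +6.4e
        top = toy.build_topology()
        base = toy.overlays.copy()
        bump = base.copy()
        sel = bump.index[
            (bump.state == "bridged")
            & bump.residue_index.isin(toy.groove_residues[0] + 1)
        ]
        bump.loc[sel, "charge_e"] += 0.2
        a = assign_charge_state(top, "bridged", base)
        b = assign_charge_state(top, "bridged", bump)
        assert b.charges.sum() - a.charges.sum() == pytest.approx(6.4)

    def test_missing_charged_residue_rejected(self):
        top = self._toy_topology()
        ov = pd.DataFrame(
            [(0, 2, "bridged", 0.1)],
            columns=["subunit", "residue_index", "state", "charge_e"],
        )
        with pytest.raises(ValueError, match="missing charged"):
            assign_charge_state(top, "bridged", ov)

    def test_bridged_state_more_attractive_above_pocket(self, toy):
        # a probe phosphate 10 A above a groove residue feels a lower
        # electrostatic energy in the bridged state
        top = toy.build_topology()
        res, r0 = interface_reference_distances(top, toy.dna_reference[1::3])
        groove_bead = res[0]
        probe = top.positions[groove_bead] + np.array([0.0, 0.0, 10.0])
        lam = 10.0 * debye_length(0.15)
        energies = {}
        for state in ("unbridged", "bridged"):
            t = assign_charge_state(top, state, toy.overlays)
            prot = np.flatnonzero(t.molecule == 0)
            energies[state] = electrostatic_energy(
                t.positions[prot], t.charges[prot], probe, [-0.6], lam
            )
        assert energies["bridged"] < energies["unbridged"]


class TestInterfaceDistances:
    def test_single_residue_reference_distance(self):
        top = build_ssdna_topology("T")  # donor of base coords only
        prot = build_protein_topology(
            _chain(3.8 * np.arange(4)[:, None] * [1, 0, 0])
        )
        base = prot.positions[0] + np.array([0.0, 5.0, 0.0])
        res, r0 = interface_reference_distances(prot, base[None, :], cutoff=10.0)
        assert 0 in res
        assert r0[list(res).index(0)] == pytest.approx(5.0)

    def test_matches_brute_force_min_scan(self, toy):
        top = toy.build_topology()
        bases = toy.dna_reference[1::3]
        res, r0 = interface_reference_distances(top, bases, cutoff=10.0)
        prot = np.flatnonzero((top.molecule == 0))
        expect = {}
        for i in prot:
            dmin = np.min(np.linalg.norm(bases - top.positions[i], axis=1))
            if dmin <= 10.0:
                expect[i] = dmin
        assert set(res.tolist()) == set(expect)
        for i, v in zip(res, r0):
            assert v == pytest.approx(expect[int(i)])

    def test_residue_beyond_cutoff_excluded(self):
        prot = build_protein_topology(
            _chain(3.8 * np.arange(4)[:, None] * [1, 0, 0])
        )
        base = prot.positions[0] + np.array([0.0, 11.0, 0.0])
        with pytest.warns(UserWarning):
            res, _ = interface_reference_distances(
                prot, base[None, :] + np.array([0, 100, 0]), cutoff=10.0
            )
        assert res.size == 0


class TestInterfacePotential:
    def test_minimum_depth_is_minus_epsilon(self):
        e = interface_contact_energy([[0.0, 0.0, 0.0]], [[6.0, 0.0, 0.0]], [6.0])
        assert e == pytest.approx(-0.2325, abs=1e-12)

    def test_value_at_twice_reference_distance(self):
        # 5/2^12 - 6/2^10 = -0.00463867...
        e = interface_contact_energy([[0.0, 0.0, 0.0]], [[12.0, 0.0, 0.0]], [6.0], 1.0)
        assert e == pytest.approx(5.0 / 4096.0 - 6.0 / 1024.0, rel=1e-12)

    def test_vanishes_at_large_separation(self):
        e = interface_contact_energy([[0.0, 0.0, 0.0]], [[1e4, 0.0, 0.0]], [6.0])
        assert abs(e) < 1e-12

    def test_coincident_pair_raises(self):
        with pytest.raises(ZeroDivisionError):
            interface_contact_energy([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]], [6.0])

    def test_isolated_pair_minimum_location(self):
        r = np.linspace(4.0, 12.0, 400)
        e = [
            interface_contact_energy([[0.0, 0.0, 0.0]], [[ri, 0.0, 0.0]], [6.0])
            for ri in r
        ]
        assert r[np.argmin(e)] == pytest.approx(6.0, abs=0.05)
        assert min(e) == pytest.approx(-0.2325, abs=1e-4)


class TestDebyeLength:
    def test_physical_constants_value_at_150mM(self):
        # independent evaluation from CODATA constants gives 0.785 nm
        assert debye_length(0.150, 300.0, 78.0) == pytest.approx(0.785, abs=0.001)

    def test_inverse_sqrt_scaling(self):
        assert debye_length(0.04) == pytest.approx(2.0 * debye_length(0.16), rel=1e-12)

    def test_monotone_in_salt(self):
        assert debye_length(0.01) > debye_length(0.3)

    def test_nonpositive_salt_rejected(self):
        with pytest.raises(ValueError):
            debye_length(0.0)


class TestElectrostatics:
    def test_neutral_pair_contributes_nothing(self):
        e = electrostatic_energy([[0, 0, 0]], [0.0], [[5, 0, 0]], [1.0], 10.0)
        assert e == 0.0

    def test_hand_evaluated_screened_coulomb(self):
        # +1e/-1e at 7.8 A with lambda = 7.8 A: Coulomb x e^-1, minus shift
        lam = 7.8
        rc = 5.0 * lam
        expected = (
            COULOMB_KCAL_A / 78.0 * (-1.0) * (np.exp(-1.0) / 7.8 - np.exp(-5.0) / rc)
        )
        e = electrostatic_energy([[0, 0, 0]], [1.0], [[7.8, 0, 0]], [-1.0], lam)
        assert e == pytest.approx(expected, rel=1e-4)

    def test_screening_weakens_with_salt(self):
        lam_lo = 10.0 * debye_length(0.01)
        lam_hi = 10.0 * debye_length(0.3)
        e_lo = electrostatic_energy([[0, 0, 0]], [1.0], [[7, 0, 0]], [-1.0], lam_lo)
        e_hi = electrostatic_energy([[0, 0, 0]], [1.0], [[7, 0, 0]], [-1.0], lam_hi)
        assert abs(e_hi) < abs(e_lo)


class TestTotalEnergy:
    def test_native_reference_has_zero_bonded_strain(self, toy):
        prot = build_protein_topology(toy.protein_structure())
        params = SimulationParams(salt_molar=0.15)
        terms, _, _ = total_energy_and_forces(prot.positions, prot, params)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-18)
        assert terms["angle"] == pytest.approx(0.0, abs=1e-18)
        assert terms["dihedral"] == pytest.approx(0.0, abs=1e-18)
        # every native contact sits at its own 12-10 minimum
        assert terms["contact"] == pytest.approx(-0.3 * len(prot.pairs), rel=1e-9)

    def test_gradient_matches_finite_differences(self, toy):
        from ssbwrap.simulate import prepare_wrapped_system

        params = SimulationParams(salt_molar=0.15)
        top = prepare_wrapped_system(toy, "bridged", params)
        rng = np.random.default_rng(13)
        x = top.positions + 0.3 * rng.standard_normal(top.positions.shape)
        _, _, forces = total_energy_and_forces(x, top, params)
        h = 1e-5
        for _ in range(20):
            i = int(rng.integers(top.n_beads))
            d = int(rng.integers(3))
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            _, ep, _ = total_energy_and_forces(xp, top, params)
            _, em, _ = total_energy_and_forces(xm, top, params)
            fd = -(ep - em) / (2 * h)
            assert fd == pytest.approx(forces[i, d], rel=1e-5, abs=1e-6)

    def test_rigid_motion_invariance(self, toy):
        from scipy.spatial.transform import Rotation

        from ssbwrap.simulate import prepare_wrapped_system

        params = SimulationParams(salt_molar=0.15, wall_radius=1e6)
        top = prepare_wrapped_system(toy, "unbridged", params)
        # drop absolute-position restraints, which legitimately break the symmetry
        top.anchor_idx = top.anchor_idx[:0]
        top.anchor_ref = top.anchor_ref[:0]
        top.anchor_k = top.anchor_k[:0]
        top.tether_idx = top.tether_idx[:0]
        top.tether_point = top.tether_point[:0]
        top.tether_r0 = top.tether_r0[:0]
        top.tether_k = top.tether_k[:0]
        rng = np.random.default_rng(7)
        x = top.positions + 0.2 * rng.standard_normal(top.positions.shape)
        _, e0, _ = total_energy_and_forces(x, top, params)
        rot = Rotation.random(random_state=11).as_matrix()
        x2 = x @ rot.T + np.array([3.0, -7.0, 11.0])
        _, e1, _ = total_energy_and_forces(x2, top, params)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_doubling_epsilon_doubles_interface_term_only(self, toy):
        from ssbwrap.simulate import prepare_wrapped_system

        p1 = SimulationParams(salt_molar=0.15, epsilon_interface=0.2325)
        p2 = SimulationParams(salt_molar=0.15, epsilon_interface=0.465)
        top = prepare_wrapped_system(toy, "bridged", p1)
        t1, _, _ = total_energy_and_forces(top.positions, top, p1)
        t2, _, _ = total_energy_and_forces(top.positions, top, p2)
        assert t2["interface"] == pytest.approx(2.0 * t1["interface"], rel=1e-12)
        for k in t1:
            if k != "interface":
                assert t2[k] == pytest.approx(t1[k], rel=1e-12)

    def test_overlapping_beads_reported(self, toy):
        top = toy.build_topology()
        x = top.positions.copy()
        far = np.flatnonzero(top.molecule == 1)[0]
        x[far] = x[0] + 1e-9
        with pytest.raises(FloatingPointError, match="overlap"):
            total_energy_and_forces(x, top, SimulationParams(salt_molar=0.15))
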