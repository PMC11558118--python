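"""Langevin integrator, restraints, and the equivalent-length spring."""

import numpy as np
import pytest

from ssbwrap.cgtop import BeadTopology, KIND_CA, build_ssdna_topology
from ssbwrap.dynamics import (
    anchor_terminal_bases,
    apply_anchor,
    equivalent_length_spring,
    run_langevin,
)
from ssbwrap.energy import SimulationParams, total_energy_and_forces


def _beads(n, spacing=4.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return BeadTopology(
        positions=pos,
        kinds=np.full(n, KIND_CA, dtype=np.int8),
        molecule=np.zeros(n, dtype=np.int8),
        subunit=np.zeros(n, dtype=np.int64),
        resid=np.arange(n, dtype=np.int64),
        resname=["GLY"] * n,
        charges=np.zeros(n),
    )


def _bonded_pair(k=100.0, r0=4.0):
    top = _beads(2)
    top.bonds = np.array([[0, 1]], dtype=np.int64)
    top.bond_r0 = np.array([r0])
    top.bond_k = np.array([k])
    return top


class TestIntegrator:
    def test_energy_conservation_without_thermostat(self):
        # zero friction: BAOAB reduces to velocity Verlet, energy drifts < 1e-4
        top = _bonded_pair()
        params = SimulationParams(friction=0.0, wall_radius=1e6, dt=0.001)
        start = top.positions.copy()
        start[1, 0] += 0.4  # stretch the bond
        traj = run_langevin(top, params, n_steps=100_000, stride=100, seed=0,
                            start_coords=start)
        total = traj.potential + traj.kinetic
        assert np.max(np.abs(total - total[0])) / abs(total[0]) < 1e-4

    def test_equipartition_in_harmonic_well(self):
        spring_k = 2.0
        top = apply_anchor(_beads(1), np.zeros((1, 3)), [0], spring_k=spring_k)
        params = SimulationParams(friction=1.0, wall_radius=1e6)
        traj = run_langevin(top, params, n_steps=1_000_000, stride=20, seed=2)
        x = traj.frames[traj.n_frames // 10 :, 0, :].astype(float)
        msd = float((x**2).mean())  # pooled over 3 dimensions
        assert msd == pytest.approx(params.kt / spring_k, rel=0.03)

    def test_bit_identical_for_same_seed(self, toy):
        from ssbwrap.simulate import prepare_wrapped_system

        params = SimulationParams(salt_molar=0.15)
        top = prepare_wrapped_system(toy, "bridged", params)
        a = run_langevin(top, params, n_steps=2000, stride=100, seed=42)
        b = run_langevin(top, params, n_steps=2000, stride=100, seed=42)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.term_energies, b.term_energies)

    def test_different_seeds_decorrelate(self):
        top = apply_anchor(_beads(1), np.zeros((1, 3)), [0], spring_k=2.0)
        params = SimulationParams(friction=1.0, wall_radius=1e6)
        a = run_langevin(top, params, n_steps=5000, stride=50, seed=1)
        b = run_langevin(top, params, n_steps=5000, stride=50, seed=2)
        assert not np.array_equal(a.frames, b.frames)

    def test_kinetic_temperature_near_target(self, toy):
        from ssbwrap.simulate import prepare_wrapped_system

        params = SimulationParams(salt_molar=0.15)
        top = prepare_wrapped_system(toy, "bridged", params)
        traj = run_langevin(top, params, n_steps=100_000, stride=100, seed=3)
        assert traj.temperature_estimate(burn_in=0.2) == pytest.approx(300.0, rel=0.02)

    def test_oversized_time_step_rejected(self):
        top = _bonded_pair()
        params = SimulationParams(dt=1.0)
        with pytest.raises(ValueError, match="stability"):
            run_langevin(top, params, n_steps=10, stride=1, seed=0)


class TestAnchors:
    def test_restraint_energy_zero_at_reference(self):
        top = apply_anchor(_beads(3), _beads(3).positions, [1], spring_k=0.3)
        terms, _, _ = total_energy_and_forces(
            top.positions, top, SimulationParams(salt_molar=0.15)
        )
        assert terms["anchor"] == 0.0

    def test_two_angstrom_displacement_arithmetic(self):
        # U = 1/2 * 0.3 * 2^2 = 0.6 kcal/mol
        top = apply_anchor(_beads(3), _beads(3).positions, [1], spring_k=0.3)
        x = top.positions.copy()
        x[1, 2] += 2.0
        terms, _, _ = total_energy_and_forces(x, top, SimulationParams(salt_molar=0.15))
        assert terms["anchor"] == pytest.approx(0.6, rel=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            apply_anchor(_beads(3), _beads(3).positions, [])

    def test_anchored_base_fluctuates_less_than_free_base(self):
        dna = build_ssdna_topology("T" * 6)
        params = SimulationParams(salt_molar=0.15, wall_radius=1e6)
        anchored = anchor_terminal_bases(dna, spring_k=0.3)
        traj = run_langevin(anchored, params, n_steps=150_000, stride=100, seed=8)
        frames = traj.frames[traj.n_frames // 5 :].astype(float)
        bases = dna.base_beads
        rmsf = np.sqrt(
            ((frames - frames.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
        )
        anchored_rmsf = rmsf[bases[-2:]].mean()
        free_rmsf = rmsf[bases[:2]].mean()
        assert anchored_rmsf < free_rmsf


class TestEquivalentLengthSpring:
    def test_rest_geometry_has_zero_spring_energy(self):
        dna = build_ssdna_topology("T" * 5)
        top = equivalent_length_spring(dna)
        terms, _, _ = total_energy_and_forces(
            top.positions, top, SimulationParams(salt_molar=0.15)
        )
        assert terms["tether"] == pytest.approx(0.0, abs=1e-18)

    def test_effective_contour_matches_one_extra_nucleotide(self):
        from ssbwrap.cgtop import SSDNA_RISE

        dna19 = equivalent_length_spring(build_ssdna_topology("T" * 19))
        dna20 = build_ssdna_topology("T" * 20)
        sugars19 = dna19.positions[dna19.kinds == 2]
        sugars20 = dna20.positions[dna20.kinds == 2]
        span19 = np.linalg.norm(
            dna19.tether_point[0] - sugars19[0]
        )
        span20 = np.linalg.norm(sugars20[-1] - sugars20[0])
        assert abs(span19 - span20) <= SSDNA_RISE

    def test_removing_spring_changes_only_that_term(self):
        dna = build_ssdna_topology("T" * 5)
        with_spring = equivalent_length_spring(dna)
        x = dna.positions + 0.5  # uniform shift stresses the fixed-point spring
        params = SimulationParams(salt_molar=0.15)
        t0, _, _ = total_energy_and_forces(x, dna, params)
        t1, _, _ = total_energy_and_forces(x, with_spring, params)
        assert t1["tether"] > 0
        for k in t0:
            if k != "tether":
                assert t1[k] == pytest.approx(t0[k], rel=1e-12)
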