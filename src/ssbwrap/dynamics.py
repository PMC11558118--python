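"""Langevin dynamics of the coarse-grained complex.

BAOAB-discretised underdamped Langevin dynamics with unit bead masses.  The
reduced time unit follows from the energy (kcal/mol) and length (Angstrom)
units; the default time step is 1% of the stiffest bond period.  Runs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .cgtop import KIND_B, KIND_S, BeadTopology
from .energy import CompiledSystem, SimulationParams

__all__ = ["Trajectory", "run_langevin", "apply_anchor", "equivalent_length_spring"]


@dataclass
class Trajectory:
    """Frames at stride plus per-frame energy breakdown."""

    frames: np.ndarray  # (n_frames, N, 3) float32, Angstrom
    term_energies: np.ndarray  # (n_frames, n_terms) kcal/mol
    kinetic: np.ndarray  # (n_frames,) kcal/mol
    stride: int
    dt: float
    seed: int
    params: SimulationParams
    diverged: bool = False

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def potential(self) -> np.ndarray:
        return self.term_energies.sum(axis=1)

    def term(self, name: str) -> np.ndarray:
        return self.term_energies[:, K.TERM_NAMES.index(name)]

    def temperature_estimate(self, burn_in: float = 0.0) -> float:
        """Kinetic temperature from <KE> = (3N/2) k_B T, in K."""
        from .constants import KB_KCAL

        start = int(burn_in * self.n_frames)
        ke = self.kinetic[start:].mean()
        n = self.frames.shape[1]
        return float(2.0 * ke / (3.0 * n * KB_KCAL))

    def burn_in_slice(self, fraction: float = 1.0 / 7.0) -> slice:
        """Frames after the equilibration prefix (default: first 1/7 dropped)."""
        return slice(int(fraction * self.n_frames), None)


def run_langevin(
    topology: BeadTopology,
    params: SimulationParams,
    n_steps: int,
    stride: int = 100,
    seed: int | None = None,
    start_coords: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the system; identical inputs + seed give identical frames.

    Initial velocities are Maxwell-Boltzmann at ``params.temperature`` drawn
    from the same seeded stream used for the thermostat noise.
    """
    if seed is None:
        seed = params.seed
    seed = int(seed) % (2**31)
    dt = params.resolve_dt(topology)
    system = CompiledSystem(topology, params, dt)
    pos = np.ascontiguousarray(
        topology.positions if start_coords is None else start_coords, dtype=float
    ).copy()
    if pos.shape != topology.positions.shape:
        raise ValueError("start_coords do not match topology")

    # Maxwell-Boltzmann velocities from a separate, deterministic stream
    rng = np.random.default_rng(seed)
    vel = rng.standard_normal(pos.shape) * np.sqrt(params.kt)

    frames, energies, kinetic, status = K.run_baoab(
        pos,
        vel,
        int(n_steps),
        int(stride),
        float(dt),
        float(params.friction),
        float(params.kt),
        seed,
        int(params.nlist_every),
        system.nlist_rc2,
        *system.baoab_args(),
    )
    return Trajectory(
        frames=frames,
        term_energies=energies,
        kinetic=kinetic,
        stride=stride,
        dt=dt,
        seed=seed,
        params=params,
        diverged=bool(status),
    )


def apply_anchor(
    topology: BeadTopology,
    reference: np.ndarray,
    bead_selection: np.ndarray,
    spring_k: float = 0.3,
) -> BeadTopology:
    """Add harmonic position restraints U = k/2 |r - r_ref|^2 per bead.

    ``reference`` gives the restraint centres for the whole system (shape
    (N, 3)) or for the selected beads only.
    """
    bead_selection = np.asarray(bead_selection, dtype=np.int64).ravel()
    if bead_selection.size == 0:
        raise ValueError("empty anchor selection")
    if np.any(bead_selection < 0) or np.any(bead_selection >= topology.n_beads):
        raise ValueError("anchor selection out of range")
    reference = np.asarray(reference, dtype=float)
    if reference.shape == topology.positions.shape:
        ref = reference[bead_selection]
    elif reference.shape == (bead_selection.size, 3):
        ref = reference
    else:
        raise ValueError("reference shape mismatch")
    out = topology.copy()
    out.anchor_idx = np.concatenate([out.anchor_idx, bead_selection])
    out.anchor_ref = np.vstack([out.anchor_ref, ref])
    out.anchor_k = np.concatenate([out.anchor_k, np.full(bead_selection.size, spring_k)])
    return out


def anchor_terminal_bases(
    topology: BeadTopology, spring_k: float = 0.3, n_bases: int = 2
) -> BeadTopology:
    """Restrain the two 3'-terminal base beads at their reference positions."""
    bases = topology.base_beads
    if bases.size < n_bases:
        raise ValueError("not enough base beads to anchor")
    sel = bases[-n_bases:]
    return apply_anchor(topology, topology.positions, sel, spring_k)


def equivalent_length_spring(
    topology: BeadTopology,
    point: np.ndarray | None = None,
    spring_k: float = 10.0,
    rest_length: float | None = None,
) -> BeadTopology:
    """Replace one missing terminal nucleotide by a short spring.

    Adds a harmonic bond of rest length one backbone rise between a fixed
    anchor site and the 3'-terminal sugar bead, making an N-nt chain
    mechanically equivalent to N+1 nt.  The default site extrapolates the
    reference backbone by one rise beyond the terminus.
    """
    dna = np.flatnonzero(topology.molecule == 1)
    if dna.size == 0:
        raise ValueError("no ssDNA in topology")
    sugars = dna[topology.kinds[dna] == KIND_S]
    from .cgtop import SSDNA_RISE

    rise = SSDNA_RISE if rest_length is None else rest_length
    last, prev = sugars[-1], sugars[-2]
    if point is None:
        direction = topology.positions[last] - topology.positions[prev]
        direction = direction / np.linalg.norm(direction)
        point = topology.positions[last] + rise * direction
    out = topology.copy()
    out.tether_idx = np.concatenate([out.tether_idx, [last]])
    out.tether_point = np.vstack([out.tether_point, np.asarray(point, dtype=float)])
    out.tether_r0 = np.concatenate([out.tether_r0, [rise]])
    out.tether_k = np.concatenate([out.tether_k, [spring_k]])
    return out
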