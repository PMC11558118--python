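"""Energy function of the protein-ssDNA complex.

The inter-molecular energy is the sum of a structure-based 12-10 interface
term (every residue with a reference distance r_i0, against every base),
Debye-Hueckel screened electrostatics between charged beads of different
molecules, and excluded volume; intra-molecular terms are the Go/ssDNA
bonded and native-contact terms carried by the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.constants as sc

from . import _kernels as K
from .constants import COULOMB_KCAL_A
from .cgtop import BeadTopology

__all__ = [
    "SimulationParams",
    "debye_length",
    "interface_contact_energy",
    "electrostatic_energy",
    "CompiledSystem",
    "total_energy_and_forces",
]


@dataclass
class SimulationParams:
    """All energy and dynamics constants for the coarse-grained model.

    Units: kcal/mol, Angstrom, K, unit bead masses; ``dt`` and ``friction``
    are in the reduced time unit set by those choices.
    """

    epsilon_interface: float = 0.2325  # kcal/mol, 12-10 interface depth
    salt_molar: float = 0.15
    relative_permittivity: float = 78.0
    temperature: float = 300.0
    exv_sigma: float = 4.0  # Angstrom
    exv_eps: float = 0.2  # kcal/mol
    contact_cutoff: float = 6.5  # Angstrom, native-contact definition
    interface_cutoff: float = 10.0  # Angstrom, r_i0 table definition
    es_cutoff_debye: float = 5.0  # electrostatic cutoff, in Debye lengths
    friction: float = 0.5  # 1 / reduced time
    dt: float | None = None  # reduced time; default from stiffest bond
    anchor_spring: float = 0.3  # kcal mol^-1 A^-2
    wall_radius: float = 85.0  # Angstrom, reflective confinement
    wall_k: float = 10.0  # kcal mol^-1 A^-2
    nlist_every: int = 40
    nlist_skin: float = 4.0  # Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "epsilon_interface", "salt_molar", "relative_permittivity",
            "temperature", "exv_sigma", "exv_eps", "contact_cutoff",
            "interface_cutoff", "es_cutoff_debye", "friction",
            "anchor_spring", "wall_radius", "wall_k",
        ):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.salt_molar <= 0:
            raise ValueError("salt_molar must be > 0")

    @property
    def kt(self) -> float:
        from .constants import KB_KCAL

        return KB_KCAL * self.temperature

    @property
    def debye_length_A(self) -> float:
        return 10.0 * debye_length(
            self.salt_molar, self.temperature, self.relative_permittivity
        )

    def stable_dt(self, max_bond_k: float = 100.0) -> float:
        """1% of the stiffest bond period (unit masses, reduced pair mass 1/2)."""
        omega = np.sqrt(2.0 * max_bond_k)
        return 0.01 * 2.0 * np.pi / omega

    def resolve_dt(self, topology: BeadTopology) -> float:
        kmax = float(topology.bond_k.max()) if topology.bond_k.size else 100.0
        dt0 = self.stable_dt(kmax)
        if self.dt is None:
            return dt0
        if self.dt > 10.0 * dt0:
            raise ValueError(
                f"dt={self.dt} exceeds the stability bound ~{10 * dt0:.4f} "
                f"for bond stiffness {kmax}"
            )
        return self.dt


def debye_length(
    salt_molar: float, temperature: float = 300.0, relative_permittivity: float = 78.0
) -> float:
    """Debye screening length in nm for a 1:1 salt of molarity ``salt_molar``.

    lambda_D = sqrt(eps0 eps_r k_B T / (2 N_A e^2 I)) with I the ionic
    strength in mol/m^3.
    """
    if salt_molar <= 0:
        raise ValueError("salt_molar must be > 0")
    ionic = salt_molar * 1000.0 * sc.Avogadro  # ions / m^3
    lam = np.sqrt(
        sc.epsilon_0 * relative_permittivity * sc.k * temperature
        / (2.0 * sc.e**2 * ionic)
    )
    return float(lam * 1e9)


def interface_contact_energy(
    protein_coords: np.ndarray,
    base_coords: np.ndarray,
    r_i0: np.ndarray,
    epsilon: float = 0.2325,
    return_gradient: bool = False,
):
    """12-10 interface energy between tabulated residues and all bases.

    ``protein_coords`` holds one row per tabulated residue (aligned with
    ``r_i0``); the sum runs over every (residue, base) combination.  The
    per-pair minimum is exactly ``-epsilon`` at separation ``r_i0``.
    """
    protein_coords = np.atleast_2d(np.asarray(protein_coords, dtype=float))
    base_coords = np.atleast_2d(np.asarray(base_coords, dtype=float))
    r_i0 = np.atleast_1d(np.asarray(r_i0, dtype=float))
    if r_i0.size == 0:
        raise ValueError("empty r_i0 table")
    if protein_coords.shape[0] != r_i0.size:
        raise ValueError("protein_coords and r_i0 must align")
    nP, nB = protein_coords.shape[0], base_coords.shape[0]
    pos = np.vstack([protein_coords, base_coords])
    forces = np.zeros_like(pos)
    e = K.interface_energy_forces(
        pos,
        np.arange(nP, dtype=np.int64),
        r_i0,
        np.arange(nP, nP + nB, dtype=np.int64),
        float(epsilon),
        forces,
    )
    d = np.linalg.norm(
        protein_coords[:, None, :] - base_coords[None, :, :], axis=-1
    )
    if np.any(d < 1e-9):
        raise ZeroDivisionError("coincident residue-base pair (r_ij = 0)")
    if return_gradient:
        return float(e), -forces[:nP], -forces[nP:]
    return float(e)


def electrostatic_energy(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    lambda_debye_A: float,
    relative_permittivity: float = 78.0,
    cutoff_debye: float = 5.0,
    return_gradient: bool = False,
):
    """Screened Coulomb energy between two charged bead groups (kcal/mol).

    U = sum_ij C q_i q_j / (eps_r r_ij) exp(-r_ij / lambda), truncated and
    shifted to zero at ``cutoff_debye`` Debye lengths.
    """
    if lambda_debye_A <= 0:
        raise ValueError("Debye length must be > 0")
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    qa = np.atleast_1d(np.asarray(charges_a, dtype=float))
    qb = np.atleast_1d(np.asarray(charges_b, dtype=float))
    na = coords_a.shape[0]
    ia, ib = np.meshgrid(np.arange(na), np.arange(qb.size), indexing="ij")
    qq = qa[ia].ravel() * qb[ib].ravel()
    keep = qq != 0.0
    pairs = np.stack([ia.ravel()[keep], ib.ravel()[keep] + na], axis=1).astype(np.int64)
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1).ravel()[keep]
    if np.any(d < 1e-9):
        raise ZeroDivisionError("coincident charged pair (r = 0)")
    pos = np.vstack([coords_a, coords_b])
    forces = np.zeros_like(pos)
    pref = COULOMB_KCAL_A * qq[keep] / relative_permittivity
    e = K.elec_energy_forces(
        pos, pairs, pref, float(lambda_debye_A), float(cutoff_debye * lambda_debye_A), forces
    )
    if return_gradient:
        return float(e), -forces
    return float(e)


@dataclass
class CompiledSystem:
    """Topology + parameters flattened into kernel-ready arrays."""

    topology: BeadTopology
    params: SimulationParams
    dt: float
    exv_candidates: np.ndarray = field(init=False)
    es_pairs: np.ndarray = field(init=False)
    es_pref: np.ndarray = field(init=False)
    es_lambda: float = field(init=False)
    es_rc: float = field(init=False)
    iface_bases: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        top, p = self.topology, self.params
        n = top.n_beads
        excl = top.bonded_exclusions(3)
        excl |= {(min(i, j), max(i, j)) for i, j in map(tuple, top.pairs)}
        iface = set(top.interface_res.tolist())
        bases = top.base_beads
        self.iface_bases = bases.astype(np.int64)
        iu, ju = np.triu_indices(n, k=1)
        mask = np.ones(iu.size, dtype=bool)
        if excl:
            ex = np.array(sorted(excl), dtype=np.int64)
            flat_ex = ex[:, 0] * n + ex[:, 1]
            flat = iu * n + ju
            mask &= ~np.isin(flat, flat_ex)
        if iface and bases.size:
            in_iface_i = np.isin(iu, list(iface)) & np.isin(ju, bases)
            in_iface_j = np.isin(ju, list(iface)) & np.isin(iu, bases)
            mask &= ~(in_iface_i | in_iface_j)
        self.exv_candidates = np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)

        # inter-molecular charged pairs plus intra-DNA phosphate repulsion
        # (phosphates separated by >= 2 nucleotides; 1-2/1-3 bonded excluded)
        qa = np.flatnonzero((top.molecule == 0) & (top.charges != 0.0))
        qb = np.flatnonzero((top.molecule == 1) & (top.charges != 0.0))
        ia, ib = np.meshgrid(qa, qb, indexing="ij")
        es = [np.stack([ia.ravel(), ib.ravel()], axis=1)]
        if qb.size > 1:
            pi, pj = np.triu_indices(qb.size, k=1)
            pp = np.stack([qb[pi], qb[pj]], axis=1)
            pp = pp[[tuple(sorted(p)) not in excl for p in map(tuple, pp)]]
            es.append(pp)
        self.es_pairs = np.vstack(es).astype(np.int64)
        self.es_pref = (
            COULOMB_KCAL_A
            * top.charges[self.es_pairs[:, 0]]
            * top.charges[self.es_pairs[:, 1]]
            / p.relative_permittivity
        )
        self.es_lambda = p.debye_length_A
        self.es_rc = p.es_cutoff_debye * self.es_lambda

    @property
    def nlist_rc2(self) -> float:
        rc = 2.0 * self.params.exv_sigma + self.params.nlist_skin
        return float(rc * rc)

    def kernel_args(self, exv_active: np.ndarray, n_exv: int) -> tuple:
        t, p = self.topology, self.params
        return (
            t.bonds, t.bond_r0, t.bond_k,
            t.angles, t.angle_t0, t.angle_k,
            t.dihedrals, t.dih_p0, t.dih_k,
            t.pairs, t.pair_r0, t.pair_eps,
            t.interface_res.astype(np.int64), t.interface_r0,
            self.iface_bases, p.epsilon_interface,
            self.es_pairs, self.es_pref, self.es_lambda, self.es_rc,
            exv_active, n_exv, p.exv_sigma, p.exv_eps,
            t.anchor_idx.astype(np.int64), t.anchor_ref, t.anchor_k,
            t.tether_idx.astype(np.int64), t.tether_point, t.tether_r0, t.tether_k,
            p.wall_radius, p.wall_k,
        )

    def baoab_args(self) -> tuple:
        """Static arrays for the integrator (which owns the neighbour list)."""
        t, p = self.topology, self.params
        return (
            self.exv_candidates,
            t.bonds, t.bond_r0, t.bond_k,
            t.angles, t.angle_t0, t.angle_k,
            t.dihedrals, t.dih_p0, t.dih_k,
            t.pairs, t.pair_r0, t.pair_eps,
            t.interface_res.astype(np.int64), t.interface_r0,
            self.iface_bases, p.epsilon_interface,
            self.es_pairs, self.es_pref, self.es_lambda, self.es_rc,
            p.exv_sigma, p.exv_eps,
            t.anchor_idx.astype(np.int64), t.anchor_ref, t.anchor_k,
            t.tether_idx.astype(np.int64), t.tether_point, t.tether_r0, t.tether_k,
            p.wall_radius, p.wall_k,
        )


def total_energy_and_forces(
    coords: np.ndarray, topology: BeadTopology, params: SimulationParams
) -> tuple[dict, float, np.ndarray]:
    """Per-term energy breakdown, total, and forces (-gradient).

    Raises on an excluded-volume overlap (coincident beads), naming the pair.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != topology.positions.shape:
        raise ValueError("coords do not match topology")
    system = CompiledSystem(topology, params, params.resolve_dt(topology))
    cand = system.exv_candidates
    d = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)
    if np.any(d < 1e-6):
        b = cand[np.argmin(d)]
        raise FloatingPointError(
            f"excluded-volume divergence: beads {int(b[0])} and {int(b[1])} overlap"
        )
    exv_active = np.empty_like(cand)
    n_exv = K.build_neighbor_list(coords, cand, system.nlist_rc2, exv_active)
    forces = np.zeros_like(coords)
    terms = K.total_energy_forces(coords, *system.kernel_args(exv_active, n_exv), forces)
    breakdown = {name: float(terms[i]) for i, name in enumerate(K.TERM_NAMES)}
    return breakdown, float(terms.sum()), forces
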