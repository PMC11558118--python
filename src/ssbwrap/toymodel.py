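"""Synthetic tetramer + wrapped ssDNA reference complex.

A compact four-subunit toy protein stands in for the real tetramer crystal
structure so the wrapping machinery is testable offline.  One subunit is
grown as a seeded self-avoiding collapsed chain, replicated by 222 (D2)
symmetry, and a poly-dT reference path is laid on a ring that passes the
surface groove of all four subunits.  Two per-residue charge overlays
emulate the two surface-charge states: "unbridged" (weak, dispersed
positive charge) and "bridged" (concentrated, net more positive groove).

The toy is NOT an OB-fold and makes no structural claim about the real
protein; it exists to exercise topology building, the interface term,
electrostatics, dynamics and the occupancy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgtop import (
    KIND_B,
    SSDNA_RISE,
    BeadTopology,
    build_protein_topology,
    build_ssdna_topology,
    interface_reference_distances,
    merge_topologies,
)

__all__ = ["ToyComplex", "make_toy_tetramer"]

_D2_ROTATIONS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


@dataclass
class ToyComplex:
    """Toy tetramer + wrapped 19-nt poly-dT reference."""

    protein_coords: np.ndarray  # (4*n_res, 3)
    n_res_per_subunit: int
    resnames: list  # per residue
    dna_sequence: str
    dna_reference: np.ndarray  # bead coords in build_ssdna_topology order
    overlays: pd.DataFrame  # subunit, residue_index, state, charge_e
    groove_residues: np.ndarray  # (4, n_groove) residue indices (0-based)
    anchor_subunit: int
    seed: int

    @property
    def n_subunits(self) -> int:
        return 4

    def protein_structure(self):
        """The tetramer as a biotite AtomArray of C-alpha pseudo-atoms."""
        import biotite.structure as bst

        n = self.protein_coords.shape[0]
        arr = bst.AtomArray(n)
        arr.coord = self.protein_coords.astype(np.float32)
        nres = self.n_res_per_subunit
        arr.chain_id = np.array(["ABCD"[i // nres] for i in range(n)])
        arr.res_id = np.array([i % nres + 1 for i in range(n)])
        arr.res_name = np.array(self.resnames)
        arr.atom_name = np.array(["CA"] * n)
        arr.element = np.array(["C"] * n)
        arr.hetero = np.zeros(n, dtype=bool)
        return arr

    def build_topology(self, **protein_kwargs) -> BeadTopology:
        """Merged protein + ssDNA topology with reference coordinates."""
        prot = build_protein_topology(self.protein_structure(), **protein_kwargs)
        dna = build_ssdna_topology(self.dna_sequence, positions=self.dna_reference)
        return merge_topologies(prot, dna)

    def half_wrapped_start(self, n_wrapped: int = 8) -> np.ndarray:
        """System start coordinates with only the 3'-side nucleotides wrapped.

        The anchored 3' stretch keeps its reference path; the remaining
        5'-side nucleotides extend along the local tangent away from the
        protein, midway between the fully wrapped and unwrapped extremes.
        """
        n_nt = len(self.dna_sequence)
        n_wrapped = min(max(2, n_wrapped), n_nt)
        dna = self.dna_reference.copy()
        first_kept = n_nt - n_wrapped  # nucleotides < first_kept are extended

        def beads_of(nt):  # bead rows of nucleotide nt (S/B or P/S/B)
            if nt == 0:
                return [0, 1]
            start = 2 + 3 * (nt - 1)
            return [start, start + 1, start + 2]

        s_kept = dna[beads_of(first_kept)[-2]]
        s_next = dna[beads_of(min(first_kept + 1, n_nt - 1))[-2]]
        tangent = s_kept - s_next
        tangent /= np.linalg.norm(tangent)
        for nt in range(first_kept - 1, -1, -1):
            shift = (first_kept - nt) * SSDNA_RISE * tangent
            ref = beads_of(first_kept)
            rows = beads_of(nt)
            # translate the kept nucleotide's bead pattern along the tangent
            for r, rr in zip(rows[-len(ref):], ref[-len(rows):]):
                dna[r] = dna[rr] + shift
        return np.vstack([self.protein_coords, dna])


def _grow_subunit(n_res: int, rng: np.random.Generator, step: float = 3.8,
                  min_sep: float = 3.5) -> np.ndarray | None:
    """Seeded self-avoiding collapsed chain inside a compact sphere."""
    radius = 2.2 * n_res ** (1.0 / 3.0) + 2.5
    pos = np.zeros((n_res, 3))
    for i in range(1, n_res):
        placed = False
        for _ in range(300):
            direction = rng.standard_normal(3)
            r = pos[i - 1]
            pull = -r / max(np.linalg.norm(r), 1e-9) * (np.linalg.norm(r) / radius) ** 2
            direction = direction / np.linalg.norm(direction) + pull
            cand = pos[i - 1] + step * direction / np.linalg.norm(direction)
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1 and np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) < min_sep:
                continue
            pos[i] = cand
            placed = True
            break
        if not placed:
            return None
    return pos - pos.mean(axis=0)


def _assemble(sub: np.ndarray, gap_target: float = 4.6) -> np.ndarray | None:
    """Place D2 images of the subunit with a controlled inter-subunit gap."""
    axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    lo, hi = 1.0, 60.0
    for _ in range(60):
        d = 0.5 * (lo + hi)
        coords = [R @ (sub + d * axis).T for R in _D2_ROTATIONS]
        coords = [c.T for c in coords]
        gap = min(
            np.min(np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1))
            for a in range(4)
            for b in range(a + 1, 4)
        )
        if abs(gap - gap_target) < 0.05:
            break
        if gap < gap_target:
            lo = d
        else:
            hi = d
    if gap < 3.5:
        return None
    return np.vstack(coords)


def _circle_distance(points: np.ndarray, radius: float) -> np.ndarray:
    """Distance from each point to the circle of ``radius`` in the z=0 plane."""
    rho = np.linalg.norm(points[:, :2], axis=1)
    return np.sqrt((rho - radius) ** 2 + points[:, 2] ** 2)


def make_toy_tetramer(
    n_res_per_subunit: int = 40,
    seed: int = 0,
    n_nt: int = 19,
    n_groove: int = 8,
    max_attempts: int = 10,
) -> ToyComplex:
    """Generate the toy complex; a pure function of its arguments.

    Raises ``RuntimeError`` if ``max_attempts`` successive seeds fail to
    produce a clash-free assembly.
    """
    if n_res_per_subunit < 30:
        raise ValueError("n_res_per_subunit must be >= 30")
    last_error = "unknown"
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed + attempt, 77]))
        sub = _grow_subunit(n_res_per_subunit, rng)
        if sub is None:
            last_error = "self-avoiding growth failed"
            continue
        tetramer = _assemble(sub)
        if tetramer is None:
            last_error = "assembly clash"
            continue

        # ssDNA ring through the equatorial surface of all four subunits
        rho_eq = np.linalg.norm(tetramer[:, :2], axis=1)
        band = np.abs(tetramer[:, 2]) < 8.0
        r_surf = float(np.max(rho_eq[band])) if np.any(band) else float(np.max(rho_eq))
        r_base = r_surf + 4.0
        r_sugar = r_base + 4.3
        dtheta = SSDNA_RISE / r_sugar
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        coords = []
        prev_s = None
        for i in range(n_nt):
            th = theta0 + i * dtheta
            s = np.array([r_sugar * np.cos(th), r_sugar * np.sin(th), 0.0])
            if i > 0:
                # phosphate at the S-S midpoint pushed radially outward, so
                # the P-S bond lengths match the ideal geometry
                mid = 0.5 * (prev_s + s)
                out = mid / np.linalg.norm(mid)
                coords.append(tuple(mid + 1.9 * out))
            coords.append(tuple(s))
            coords.append((r_base * np.cos(th), r_base * np.sin(th), 0.0))
            prev_s = s
        dna_ref = np.asarray(coords)
        if np.min(
            np.linalg.norm(tetramer[:, None, :] - dna_ref[None, :, :], axis=-1)
        ) < 3.5:
            last_error = "DNA path clash"
            continue

        # groove = residues facing the base ring, per subunit
        nres = n_res_per_subunit
        dist_ring = _circle_distance(tetramer, r_base)
        groove = np.empty((4, n_groove), dtype=np.int64)
        for s in range(4):
            local = dist_ring[s * nres : (s + 1) * nres]
            groove[s] = np.sort(np.argsort(local)[:n_groove])
        # groove is identical across subunits by symmetry; "near" residues
        # flank it, and dispersed residues face away from the ring
        order = np.argsort(dist_ring[:nres])
        near = np.sort(order[n_groove : n_groove + 4])
        far = np.sort(order[-n_groove:])

        resnames_sub = np.array(["GLY"] * nres, dtype=object)
        resnames_sub[groove[0]] = "ARG"
        resnames_sub[near] = "GLU"
        resnames_sub[far] = "LYS"
        resnames = list(resnames_sub) * 4

        # unbridged: positive charge dispersed off the groove plus weak acidic
        # patches flanking it (a weakly/patchily positive surface); bridged:
        # the positive charge concentrates in the groove
        rows = []
        for s in range(4):
            for r in groove[0]:
                rows.append((s, int(r) + 1, "unbridged", 0.0))
                rows.append((s, int(r) + 1, "bridged", 0.8))
            for r in near:
                rows.append((s, int(r) + 1, "unbridged", -0.3))
                rows.append((s, int(r) + 1, "bridged", 0.0))
            for r in far:
                rows.append((s, int(r) + 1, "unbridged", 0.2))
                rows.append((s, int(r) + 1, "bridged", 0.0))
        overlays = pd.DataFrame(
            rows, columns=["subunit", "residue_index", "state", "charge_e"]
        )

        base_ref = dna_ref[1::3]  # bead order: S0 B0, then P S B per nt
        # anchor subunit: nearest to the 3'-terminal base
        cent = tetramer.reshape(4, nres, 3).mean(axis=1)
        anchor_subunit = int(
            np.argmin(np.linalg.norm(cent - base_ref[-1][None, :], axis=1))
        )
        return ToyComplex(
            protein_coords=tetramer,
            n_res_per_subunit=nres,
            resnames=resnames,
            dna_sequence="T" * n_nt,
            dna_reference=dna_ref,
            overlays=overlays,
            groove_residues=groove,
            anchor_subunit=anchor_subunit,
            seed=seed,
        )
    raise RuntimeError(
        f"could not assemble toy tetramer after {max_attempts} attempts ({last_error})"
    )
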