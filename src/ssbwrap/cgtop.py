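"""Coarse-grained topologies: one bead per protein residue (C-alpha), three
beads per ssDNA nucleotide (phosphate, sugar, base).

The protein is a plain C-alpha Go model: harmonic bonds/angles/dihedrals about
their native values plus 12-10 native-contact attractions.  The ssDNA reduces
a three-site-per-nucleotide representation to bonds, angles, nearest-neighbour
base stacking, excluded volume and phosphate charges, which is sufficient for
a non-base-pairing homopolymer (poly-dT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KIND_CA",
    "KIND_P",
    "KIND_S",
    "KIND_B",
    "BeadTopology",
    "build_protein_topology",
    "build_ssdna_topology",
    "merge_topologies",
    "assign_charge_state",
    "interface_reference_distances",
]

KIND_CA, KIND_P, KIND_S, KIND_B = 0, 1, 2, 3
_KIND_NAMES = {KIND_CA: "CA", KIND_P: "P", KIND_S: "S", KIND_B: "B"}

#: default residue charges (e) at neutral pH; His neutral (epsilon-protonated)
RESIDUE_CHARGES = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0, "HIS": 0.0}

#: default phosphate bead charge (e), three-site-per-nucleotide convention
PHOSPHATE_CHARGE = -0.6

# ideal ssDNA geometry (Angstrom)
SSDNA_RISE = 6.3
_P_PERP = 1.9
_SB_DIST = 4.3


def _empty_i(shape):
    return np.empty(shape, dtype=np.int64)


@dataclass
class BeadTopology:
    """Beads plus every bonded/native interaction acting between them."""

    positions: np.ndarray  # (N,3) native/reference coords, Angstrom
    kinds: np.ndarray  # (N,) int8: CA/P/S/B
    molecule: np.ndarray  # (N,) 0 = protein, 1 = DNA
    subunit: np.ndarray  # (N,) subunit index, -1 for DNA
    resid: np.ndarray  # (N,) residue / nucleotide index within chain
    resname: list  # per-bead residue name
    charges: np.ndarray  # (N,) e
    bonds: np.ndarray = field(default_factory=lambda: _empty_i((0, 2)))
    bond_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    angles: np.ndarray = field(default_factory=lambda: _empty_i((0, 3)))
    angle_t0: np.ndarray = field(default_factory=lambda: np.empty(0))
    angle_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    dihedrals: np.ndarray = field(default_factory=lambda: _empty_i((0, 4)))
    dih_p0: np.ndarray = field(default_factory=lambda: np.empty(0))
    dih_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    pairs: np.ndarray = field(default_factory=lambda: _empty_i((0, 2)))
    pair_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_eps: np.ndarray = field(default_factory=lambda: np.empty(0))
    # interface 12-10 table (set via interface_reference_distances)
    interface_res: np.ndarray = field(default_factory=lambda: _empty_i(0))
    interface_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    # restraints
    anchor_idx: np.ndarray = field(default_factory=lambda: _empty_i(0))
    anchor_ref: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anchor_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    tether_idx: np.ndarray = field(default_factory=lambda: _empty_i(0))
    tether_point: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    tether_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    tether_k: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def base_beads(self) -> np.ndarray:
        """Indices of DNA base beads."""
        return np.flatnonzero((self.molecule == 1) & (self.kinds == KIND_B))

    @property
    def n_subunits(self) -> int:
        s = self.subunit[self.subunit >= 0]
        return int(s.max()) + 1 if s.size else 0

    def copy(self) -> "BeadTopology":
        kw = {}
        for f_ in self.__dataclass_fields__:
            v = getattr(self, f_)
            kw[f_] = v.copy() if isinstance(v, np.ndarray) else list(v)
        return BeadTopology(**kw)

    def bonded_exclusions(self, n_bonds_away: int = 3) -> set:
        """Pairs within ``n_bonds_away`` bonds of each other (1-2/1-3/1-4)."""
        adj: dict[int, set[int]] = {}
        for i, j in self.bonds:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        excl = set()
        for start in adj:
            seen = {start}
            frontier = {start}
            for _ in range(n_bonds_away):
                frontier = {k for f_ in frontier for k in adj.get(f_, ())} - seen
                seen |= frontier
            for other in seen - {start}:
                excl.add((min(start, other), max(start, other)))
        return excl


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or nb2 < 1e-9:
        return 0.0  # collinear: native value undefined, use 0
    return float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))


def build_protein_topology(
    structure,
    contact_cutoff: float = 6.5,
    min_seq_sep: int = 4,
    bond_k: float = 100.0,
    angle_k: float = 20.0,
    dihedral_k: float = 1.0,
    contact_eps: float = 0.3,
    max_bond_length: float = 4.5,
) -> BeadTopology:
    """C-alpha Go topology from a structure.

    ``structure`` is a biotite ``AtomArray`` or a path to a PDB file.  Native
    contacts join residue pairs whose C-alpha distance is at most
    ``contact_cutoff`` with sequence separation >= ``min_seq_sep`` (any
    separation across chains).
    """
    import biotite.structure as bst

    if not isinstance(structure, bst.AtomArray):
        from biotite.structure.io.pdb import PDBFile

        structure = PDBFile.read(str(structure)).get_structure(model=1)
    ca = structure[structure.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError("structure contains no C-alpha atoms")
    pos = np.asarray(ca.coord, dtype=float)
    chain_ids = ca.chain_id
    res_ids = np.asarray(ca.res_id, dtype=int)
    resnames = [str(r) for r in ca.res_name]
    n = pos.shape[0]

    # map chains to subunit indices preserving file order
    uniq = list(dict.fromkeys(chain_ids))
    subunit = np.array([uniq.index(c) for c in chain_ids], dtype=np.int64)

    charges = np.array([RESIDUE_CHARGES.get(rn, 0.0) for rn in resnames])

    bonds, angles, dihedrals = [], [], []
    for i in range(n - 1):
        if subunit[i] != subunit[i + 1]:
            continue
        if np.linalg.norm(pos[i + 1] - pos[i]) > max_bond_length:
            warnings.warn(
                f"chain break between residues {res_ids[i]} and {res_ids[i+1]}; "
                "bond skipped",
                stacklevel=2,
            )
            continue
        bonds.append((i, i + 1))
    bond_set = set(bonds)
    for i in range(n - 2):
        if (i, i + 1) in bond_set and (i + 1, i + 2) in bond_set:
            angles.append((i, i + 1, i + 2))
    for i in range(n - 3):
        if all((i + k, i + k + 1) in bond_set for k in range(3)):
            dihedrals.append((i, i + 1, i + 2, i + 3))

    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    # native contacts
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    same_chain = subunit[iu] == subunit[ju]
    sep_ok = np.where(same_chain, np.abs(iu - ju) >= min_seq_sep, True)
    keep = (d[iu, ju] <= contact_cutoff) & sep_ok
    pairs = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)

    return BeadTopology(
        positions=pos,
        kinds=np.full(n, KIND_CA, dtype=np.int8),
        molecule=np.zeros(n, dtype=np.int8),
        subunit=subunit,
        resid=res_ids.astype(np.int64),
        resname=resnames,
        charges=charges,
        bonds=bonds,
        bond_r0=np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
        if bonds.size
        else np.empty(0),
        bond_k=np.full(bonds.shape[0], bond_k),
        angles=angles,
        angle_t0=np.array([_angle(pos[a], pos[b], pos[c]) for a, b, c in angles]),
        angle_k=np.full(angles.shape[0], angle_k),
        dihedrals=dihedrals,
        dih_p0=np.array([_dihedral(pos[a], pos[b], pos[c], pos[d_]) for a, b, c, d_ in dihedrals]),
        dih_k=np.full(dihedrals.shape[0], dihedral_k),
        pairs=pairs,
        pair_r0=d[pairs[:, 0], pairs[:, 1]] if pairs.size else np.empty(0),
        pair_eps=np.full(pairs.shape[0], contact_eps),
    )


def build_ssdna_topology(
    sequence: str,
    rise: float = SSDNA_RISE,
    bond_k: float = 100.0,
    angle_k: float = 1.5,
    stacking_eps: float = 0.5,
    positions: np.ndarray | None = None,
) -> BeadTopology:
    """Three-site-per-nucleotide ssDNA topology from a sequence.

    The 5' terminal nucleotide lacks its leading phosphate, giving 3N-1
    beads.  Native bond lengths / angles come from an ideal extended
    geometry; pass ``positions`` (same bead order: S0 B0, then P S B per
    nucleotide) to use other reference coordinates for the bead layout
    while keeping the ideal-geometry native values.
    """
    sequence = sequence.upper()
    if not sequence or any(c not in "ACGT" for c in sequence):
        raise ValueError(f"invalid nucleotide sequence {sequence!r}")
    n = len(sequence)

    ideal = []
    kinds, resid, resname = [], [], []
    index = {}  # (kind, nt) -> bead index
    for i in range(n):
        if i > 0:
            index[("P", i)] = len(ideal)
            ideal.append(((i - 0.5) * rise, _P_PERP, 0.0))
            kinds.append(KIND_P)
            resid.append(i)
            resname.append("D" + sequence[i])
        index[("S", i)] = len(ideal)
        ideal.append((i * rise, 0.0, 0.0))
        kinds.append(KIND_S)
        resid.append(i)
        resname.append("D" + sequence[i])
        index[("B", i)] = len(ideal)
        ideal.append((i * rise, -_SB_DIST, 0.0))
        kinds.append(KIND_B)
        resid.append(i)
        resname.append("D" + sequence[i])
    ideal = np.asarray(ideal, dtype=float)
    pos = ideal if positions is None else np.asarray(positions, dtype=float)
    if pos.shape != ideal.shape:
        raise ValueError("positions do not match the bead layout")

    bonds, angles = [], []
    for i in range(n):
        bonds.append((index[("S", i)], index[("B", i)]))
        if i > 0:
            bonds.append((index[("S", i - 1)], index[("P", i)]))
            bonds.append((index[("P", i)], index[("S", i)]))
    for i in range(1, n):
        angles.append((index[("S", i - 1)], index[("P", i)], index[("S", i)]))
        angles.append((index[("P", i)], index[("S", i)], index[("B", i)]))
        if i < n - 1:
            angles.append((index[("P", i)], index[("S", i)], index[("P", i + 1)]))
    stack = [(index[("B", i)], index[("B", i + 1)]) for i in range(n - 1)]

    bonds = np.array(bonds, dtype=np.int64)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    stack = np.array(stack, dtype=np.int64).reshape(-1, 2)

    charges = np.where(np.array(kinds) == KIND_P, PHOSPHATE_CHARGE, 0.0)
    return BeadTopology(
        positions=pos,
        kinds=np.array(kinds, dtype=np.int8),
        molecule=np.ones(len(kinds), dtype=np.int8),
        subunit=np.full(len(kinds), -1, dtype=np.int64),
        resid=np.array(resid, dtype=np.int64),
        resname=resname,
        charges=charges,
        bonds=bonds,
        bond_r0=np.linalg.norm(ideal[bonds[:, 0]] - ideal[bonds[:, 1]], axis=1),
        bond_k=np.full(bonds.shape[0], bond_k),
        angles=angles,
        angle_t0=np.array([_angle(ideal[a], ideal[b], ideal[c]) for a, b, c in angles]),
        angle_k=np.full(angles.shape[0], angle_k),
        pairs=stack,
        pair_r0=np.linalg.norm(ideal[stack[:, 0]] - ideal[stack[:, 1]], axis=1)
        if stack.size
        else np.empty(0),
        pair_eps=np.full(stack.shape[0], stacking_eps),
    )


def merge_topologies(protein: BeadTopology, dna: BeadTopology) -> BeadTopology:
    """Concatenate protein and DNA topologies, offsetting DNA bead indices."""
    off = protein.n_beads
    out = protein.copy()
    out.positions = np.vstack([protein.positions, dna.positions])
    for name in ("kinds", "molecule", "subunit", "resid", "charges"):
        setattr(out, name, np.concatenate([getattr(protein, name), getattr(dna, name)]))
    out.resname = list(protein.resname) + list(dna.resname)
    for tbl, cols in (
        ("bonds", ("bond_r0", "bond_k")),
        ("angles", ("angle_t0", "angle_k")),
        ("dihedrals", ("dih_p0", "dih_k")),
        ("pairs", ("pair_r0", "pair_eps")),
    ):
        a, b = getattr(protein, tbl), getattr(dna, tbl)
        setattr(out, tbl, np.vstack([a, b + off]) if b.size else a.copy())
        for c in cols:
            setattr(out, c, np.concatenate([getattr(protein, c), getattr(dna, c)]))
    for idx_name, extra in (
        ("anchor_idx", ("anchor_ref", "anchor_k")),
        ("tether_idx", ("tether_point", "tether_r0", "tether_k")),
    ):
        a, b = getattr(protein, idx_name), getattr(dna, idx_name)
        setattr(out, idx_name, np.concatenate([a, b + off]))
        for c in extra:
            pa, pb = getattr(protein, c), getattr(dna, c)
            setattr(out, c, np.concatenate([pa, pb]) if pa.ndim == 1 else np.vstack([pa, pb]))
    return out


def assign_charge_state(
    topology: BeadTopology, state: str, overlay: pd.DataFrame
) -> BeadTopology:
    """Replace protein bead charges with a per-state charge overlay.

    ``overlay`` has columns ``subunit, residue_index, state, charge_e``; it
    must cover every residue that carries a default charge, otherwise the
    overlay is rejected.  DNA charges are untouched.
    """
    required = {"subunit", "residue_index", "state", "charge_e"}
    if not required.issubset(overlay.columns):
        raise ValueError(f"overlay must have columns {sorted(required)}")
    sel = overlay[overlay["state"] == state]
    if sel.empty:
        raise ValueError(f"overlay has no rows for state {state!r}")
    table = {
        (int(r.subunit), int(r.residue_index)): float(r.charge_e)
        for r in sel.itertuples()
    }
    prot = np.flatnonzero(topology.molecule == 0)
    default_charged = {
        (int(topology.subunit[i]), int(topology.resid[i]))
        for i in prot
        if RESIDUE_CHARGES.get(topology.resname[i], 0.0) != 0.0
    }
    missing = default_charged - set(table)
    if missing:
        raise ValueError(f"overlay (state {state!r}) missing charged residues: {sorted(missing)[:5]}")
    out = topology.copy()
    for i in prot:
        out.charges[i] = table.get((int(topology.subunit[i]), int(topology.resid[i])), 0.0)
    return out


def interface_reference_distances(
    protein: BeadTopology,
    dna_reference: np.ndarray,
    cutoff: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue reference distance to the nearest base in the reference.

    ``dna_reference`` holds the base-bead coordinates of the bound (native)
    complex.  Residues farther than ``cutoff`` from every base are excluded:
    only residues forming native contacts with bases enter the interface sum.
    Returns (C-alpha bead indices, r_i0 values).
    """
    dna_reference = np.asarray(dna_reference, dtype=float).reshape(-1, 3)
    if dna_reference.size == 0:
        raise ValueError("reference complex has no base coordinates")
    ca = np.flatnonzero((protein.molecule == 0) & (protein.kinds == KIND_CA))
    d = np.linalg.norm(
        protein.positions[ca][:, None, :] - dna_reference[None, :, :], axis=-1
    )
    dmin = d.min(axis=1)
    keep = dmin <= cutoff
    if not np.any(keep):
        warnings.warn("no residue within interface cutoff of any base", stacklevel=2)
    return ca[keep], dmin[keep]
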