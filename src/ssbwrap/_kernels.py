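"""Numba kernels: energy terms, analytic forces, and the BAOAB integrator.

All kernels work in the coarse-grained unit system (kcal/mol, Angstrom,
unit bead masses, reduced time).  Energy terms are indexed by the
``TERM_*`` constants; every kernel adds its forces into a shared array and
returns its energy so the per-term breakdown is exact.
"""

import numpy as np
from numba import njit

N_TERMS = 10
(
    TERM_BOND,
    TERM_ANGLE,
    TERM_DIHEDRAL,
    TERM_CONTACT,
    TERM_INTERFACE,
    TERM_ELEC,
    TERM_EXV,
    TERM_ANCHOR,
    TERM_TETHER,
    TERM_WALL,
) = range(N_TERMS)

TERM_NAMES = (
    "bond",
    "angle",
    "dihedral",
    "contact",
    "interface",
    "elec",
    "exv",
    "anchor",
    "tether",
    "wall",
)


@njit(cache=True, fastmath=True)
def bond_energy_forces(pos, bonds, r0, k, forces):
    e = 0.0
    for n in range(bonds.shape[0]):
        i, j = bonds[n, 0], bonds[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += 0.5 * k[n] * dr * dr
        if r > 1e-12:
            fmag = -k[n] * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def angle_energy_forces(pos, angles, t0, k, forces):
    e = 0.0
    for n in range(angles.shape[0]):
        i, j, l = angles[n, 0], angles[n, 1], angles[n, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[l, 0] - pos[j, 0]
        vy = pos[l, 1] - pos[j, 1]
        vz = pos[l, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - t0[n]
        e += 0.5 * k[n] * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            continue  # collinear: force direction undefined, energy still counted
        coeff = -k[n] * dth / s
        # d(theta)/dr_i = (c*u/nu - v/nv)/nu ; force = -dU/dtheta * dtheta/dr
        gi_x = (c * ux / nu - vx / nv) / nu
        gi_y = (c * uy / nu - vy / nv) / nu
        gi_z = (c * uz / nu - vz / nv) / nu
        gl_x = (c * vx / nv - ux / nu) / nv
        gl_y = (c * vy / nv - uy / nu) / nv
        gl_z = (c * vz / nv - uz / nu) / nv
        forces[i, 0] += coeff * gi_x
        forces[i, 1] += coeff * gi_y
        forces[i, 2] += coeff * gi_z
        forces[l, 0] += coeff * gl_x
        forces[l, 1] += coeff * gl_y
        forces[l, 2] += coeff * gl_z
        forces[j, 0] -= coeff * (gi_x + gl_x)
        forces[j, 1] -= coeff * (gi_y + gl_y)
        forces[j, 2] -= coeff * (gi_z + gl_z)
    return e


@njit(cache=True, fastmath=True)
def dihedral_energy_forces(pos, dihedrals, p0, k, forces):
    e = 0.0
    for n in range(dihedrals.shape[0]):
        i1, i2, i3, i4 = dihedrals[n, 0], dihedrals[n, 1], dihedrals[n, 2], dihedrals[n, 3]
        b1x = pos[i2, 0] - pos[i1, 0]
        b1y = pos[i2, 1] - pos[i1, 1]
        b1z = pos[i2, 2] - pos[i1, 2]
        b2x = pos[i3, 0] - pos[i2, 0]
        b2y = pos[i3, 1] - pos[i2, 1]
        b2z = pos[i3, 2] - pos[i2, 2]
        b3x = pos[i4, 0] - pos[i3, 0]
        b3y = pos[i4, 1] - pos[i3, 1]
        b3z = pos[i4, 2] - pos[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2sq = b2x * b2x + b2y * b2y + b2z * b2z
        b2n = np.sqrt(b2sq)
        if n1sq < 1e-12 or n2sq < 1e-12 or b2n < 1e-12:
            continue  # degenerate (collinear) geometry
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sphi = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        cphi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sphi, cphi)
        dphi = phi - p0[n]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi < -np.pi:
            dphi += 2.0 * np.pi
        e += 0.5 * k[n] * dphi * dphi
        du = k[n] * dphi  # dU/dphi
        c1 = du * b2n / n1sq
        c4 = -du * b2n / n2sq
        f1x, f1y, f1z = c1 * n1x, c1 * n1y, c1 * n1z
        f4x, f4y, f4z = c4 * n2x, c4 * n2y, c4 * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        u = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i2, 0] += -f1x - t * f1x + u * f4x
        forces[i2, 1] += -f1y - t * f1y + u * f4y
        forces[i2, 2] += -f1z - t * f1z + u * f4z
        forces[i3, 0] += -f4x + t * f1x - u * f4x
        forces[i3, 1] += -f4y + t * f1y - u * f4y
        forces[i3, 2] += -f4z + t * f1z - u * f4z
        forces[i4, 0] += f4x
        forces[i4, 1] += f4y
        forces[i4, 2] += f4z
    return e


@njit(cache=True, fastmath=True)
def pair1210_energy_forces(pos, pairs, r0, eps, forces):
    """12-10 potential eps*[5 (r0/r)^12 - 6 (r0/r)^10]; minimum -eps at r0."""
    e = 0.0
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        q = r0[n] / r
        q2 = q * q
        q10 = q2 * q2 * q2 * q2 * q2
        q12 = q10 * q2
        e += eps[n] * (5.0 * q12 - 6.0 * q10)
        # dU/dr = 60 eps (q10 - q12)/r ; force = -dU/dr * rhat
        fmag = -60.0 * eps[n] * (q10 - q12) / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def interface_energy_forces(pos, res_idx, r_i0, base_idx, eps, forces):
    """Structure-based interface term: every tabulated residue with every base."""
    e = 0.0
    for a in range(res_idx.shape[0]):
        i = res_idx[a]
        ri0 = r_i0[a]
        for b in range(base_idx.shape[0]):
            j = base_idx[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            q = ri0 / r
            q2 = q * q
            q10 = q2 * q2 * q2 * q2 * q2
            q12 = q10 * q2
            e += eps * (5.0 * q12 - 6.0 * q10)
            fmag = -60.0 * eps * (q10 - q12) / r2
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def elec_energy_forces(pos, pairs, pref, lam, rc, forces):
    """Debye-Hueckel screened Coulomb, shifted to zero at the cutoff.

    ``pref[n] = C q_i q_j / eps_r`` in kcal/mol * Angstrom.
    """
    e = 0.0
    rc2 = rc * rc
    shift_fac = np.exp(-rc / lam) / rc  # per-pair shift = pref * shift_fac
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        e += pref[n] / r * np.exp(-r / lam) - pref[n] * shift_fac
        # dU/dr = -pref e^{-r/lam} (1/r^2 + 1/(r lam))
        fmag = pref[n] * np.exp(-r / lam) * (1.0 / r2 + 1.0 / (r * lam)) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def exv_energy_forces(pos, pairs, n_pairs, sigma, eps, forces):
    """Purely repulsive (sigma/r)^12, truncated and shifted at 2 sigma."""
    e = 0.0
    rc = 2.0 * sigma
    rc2 = rc * rc
    shift = eps / 4096.0  # eps*(1/2)^12
    for n in range(n_pairs):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        s2 = sigma * sigma / r2
        s12 = s2 * s2 * s2
        s12 = s12 * s12
        e += eps * s12 - shift
        fmag = 12.0 * eps * s12 / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def anchor_energy_forces(pos, idx, ref, k, forces):
    e = 0.0
    for n in range(idx.shape[0]):
        i = idx[n]
        dx = pos[i, 0] - ref[n, 0]
        dy = pos[i, 1] - ref[n, 1]
        dz = pos[i, 2] - ref[n, 2]
        e += 0.5 * k[n] * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= k[n] * dx
        forces[i, 1] -= k[n] * dy
        forces[i, 2] -= k[n] * dz
    return e


@njit(cache=True, fastmath=True)
def tether_energy_forces(pos, idx, point, r0, k, forces):
    """Harmonic spring of nonzero rest length to a fixed point."""
    e = 0.0
    for n in range(idx.shape[0]):
        i = idx[n]
        dx = pos[i, 0] - point[n, 0]
        dy = pos[i, 1] - point[n, 1]
        dz = pos[i, 2] - point[n, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += 0.5 * k[n] * dr * dr
        if r > 1e-12:
            fmag = -k[n] * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
    return e


@njit(cache=True, fastmath=True)
def wall_energy_forces(pos, radius, k, forces):
    """Half-harmonic spherical wall about the origin."""
    e = 0.0
    for i in range(pos.shape[0]):
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r > radius:
            dr = r - radius
            e += 0.5 * k * dr * dr
            fmag = -k * dr / r
            forces[i, 0] += fmag * pos[i, 0]
            forces[i, 1] += fmag * pos[i, 1]
            forces[i, 2] += fmag * pos[i, 2]
    return e


@njit(cache=True, fastmath=True)
def build_neighbor_list(pos, candidates, rc2, out):
    n = 0
    for m in range(candidates.shape[0]):
        i, j = candidates[m, 0], candidates[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx * dx + dy * dy + dz * dz < rc2:
            out[n, 0] = i
            out[n, 1] = j
            n += 1
    return n


@njit(cache=True, fastmath=True)
def total_energy_forces(
    pos,
    bonds, bond_r0, bond_k,
    angles, angle_t0, angle_k,
    dihedrals, dih_p0, dih_k,
    pairs, pair_r0, pair_eps,
    iface_res, iface_r0, iface_bases, iface_eps,
    es_pairs, es_pref, es_lambda, es_rc,
    exv_pairs, n_exv, exv_sigma, exv_eps,
    anchor_idx, anchor_ref, anchor_k,
    tether_idx, tether_point, tether_r0, tether_k,
    wall_radius, wall_k,
    forces,
):
    forces[:, :] = 0.0
    terms = np.zeros(N_TERMS)
    terms[TERM_BOND] = bond_energy_forces(pos, bonds, bond_r0, bond_k, forces)
    terms[TERM_ANGLE] = angle_energy_forces(pos, angles, angle_t0, angle_k, forces)
    terms[TERM_DIHEDRAL] = dihedral_energy_forces(pos, dihedrals, dih_p0, dih_k, forces)
    terms[TERM_CONTACT] = pair1210_energy_forces(pos, pairs, pair_r0, pair_eps, forces)
    terms[TERM_INTERFACE] = interface_energy_forces(
        pos, iface_res, iface_r0, iface_bases, iface_eps, forces
    )
    terms[TERM_ELEC] = elec_energy_forces(pos, es_pairs, es_pref, es_lambda, es_rc, forces)
    terms[TERM_EXV] = exv_energy_forces(pos, exv_pairs, n_exv, exv_sigma, exv_eps, forces)
    terms[TERM_ANCHOR] = anchor_energy_forces(pos, anchor_idx, anchor_ref, anchor_k, forces)
    terms[TERM_TETHER] = tether_energy_forces(
        pos, tether_idx, tether_point, tether_r0, tether_k, forces
    )
    terms[TERM_WALL] = wall_energy_forces(pos, wall_radius, wall_k, forces)
    return terms


@njit(cache=True, fastmath=True)
def run_baoab(
    pos,
    vel,
    n_steps,
    stride,
    dt,
    gamma,
    kt,
    seed,
    nlist_every,
    nlist_rc2,
    exv_candidates,
    bonds, bond_r0, bond_k,
    angles, angle_t0, angle_k,
    dihedrals, dih_p0, dih_k,
    pairs, pair_r0, pair_eps,
    iface_res, iface_r0, iface_bases, iface_eps,
    es_pairs, es_pref, es_lambda, es_rc,
    exv_sigma, exv_eps,
    anchor_idx, anchor_ref, anchor_k,
    tether_idx, tether_point, tether_r0, tether_k,
    wall_radius, wall_k,
):
    """BAOAB-discretised underdamped Langevin dynamics, unit masses.

    Returns (frames float32, per-frame term energies, per-frame kinetic
    energy, status) with status 0 = completed, 1 = energy diverged.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_frames = n_steps // stride + 1
    frames = np.zeros((n_frames, n, 3), dtype=np.float32)
    energies = np.zeros((n_frames, N_TERMS))
    kinetic = np.zeros(n_frames)
    forces = np.zeros((n, 3))
    exv_active = np.zeros_like(exv_candidates)
    n_exv = build_neighbor_list(pos, exv_candidates, nlist_rc2, exv_active)

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kt)

    terms = total_energy_forces(
        pos,
        bonds, bond_r0, bond_k,
        angles, angle_t0, angle_k,
        dihedrals, dih_p0, dih_k,
        pairs, pair_r0, pair_eps,
        iface_res, iface_r0, iface_bases, iface_eps,
        es_pairs, es_pref, es_lambda, es_rc,
        exv_active, n_exv, exv_sigma, exv_eps,
        anchor_idx, anchor_ref, anchor_k,
        tether_idx, tether_point, tether_r0, tether_k,
        wall_radius, wall_k,
        forces,
    )
    frames[0] = pos.astype(np.float32)
    energies[0] = terms
    kinetic[0] = 0.5 * np.sum(vel * vel)
    frame = 1
    status = 0

    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    v = vel[i, d] + half * forces[i, d]  # B
                    x = pos[i, d] + half * v  # A
                    v = c1 * v + c2 * np.random.standard_normal()  # O
                    pos[i, d] = x + half * v  # A
                    vel[i, d] = v
        else:
            for i in range(n):
                for d in range(3):
                    v = vel[i, d] + half * forces[i, d]
                    pos[i, d] += dt * v
                    vel[i, d] = v
        # rebuild neighbours then force eval
        if step % nlist_every == 0:
            n_exv = build_neighbor_list(pos, exv_candidates, nlist_rc2, exv_active)
        terms = total_energy_forces(
            pos,
            bonds, bond_r0, bond_k,
            angles, angle_t0, angle_k,
            dihedrals, dih_p0, dih_k,
            pairs, pair_r0, pair_eps,
            iface_res, iface_r0, iface_bases, iface_eps,
            es_pairs, es_pref, es_lambda, es_rc,
            exv_active, n_exv, exv_sigma, exv_eps,
            anchor_idx, anchor_ref, anchor_k,
            tether_idx, tether_point, tether_r0, tether_k,
            wall_radius, wall_k,
            forces,
        )
        # B: half kick with the fresh forces
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
        if step % stride == 0:
            tot = 0.0
            for t in range(N_TERMS):
                tot += terms[t]
            if not np.isfinite(tot) or np.abs(tot) > 1e10:
                status = 1
                return frames[:frame], energies[:frame], kinetic[:frame], status
            frames[frame] = pos.astype(np.float32)
            energies[frame] = terms
            kinetic[frame] = 0.5 * np.sum(vel * vel)
            frame += 1
    return frames[:frame], energies[:frame], kinetic[:frame], status
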