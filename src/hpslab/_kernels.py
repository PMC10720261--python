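"""Numba-compiled inner loops: neighbor lists, pair forces, Langevin stepping.

Everything here operates on plain numpy arrays so the hot loops stay free of
Python objects.  Conventions:

* positions are stored *unwrapped*; all pair distances use the minimum-image
  convention in an orthorhombic periodic box, so coordinates may lie outside
  the primary cell.
* the short-range potential is the Ashbaugh–Hatch (hydropathy-scaled
  Lennard-Jones) form; electrostatics are Debye–Hückel screened Coulomb;
  bonds are harmonic.  Both nonbonded terms are truncated (not shifted) at
  their cutoffs.
* rigid bodies are propagated as center-of-mass + quaternion with body-frame
  angular momentum, using a no-squish free-rotor splitting inside a
  BAOAB-style Langevin scheme.  Because the per-bead friction is
  gamma_i = m_i / tau, the rigid-group friction reduces exactly to
  -(M/tau) V on the COM and -(I/tau) omega on the rotation, so one uniform
  Ornstein–Uhlenbeck factor exp(-dt/tau) thermostats every degree of freedom.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fatal-overlap threshold, nm
OVERLAP_R = 0.05
# max per-step displacement before the integrator aborts, nm
MAX_STEP_DISP = 0.5


@njit(cache=True, inline="always")
def _min_image(d, box):
    out = np.empty(3)
    for k in range(3):
        out[k] = d[k] - box[k] * np.rint(d[k] / box[k])
    return out


@njit(cache=True)
def _is_excluded(i, j, excl_indptr, excl_indices):
    lo = excl_indptr[i]
    hi = excl_indptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = excl_indices[mid]
        if v == j:
            return True
        elif v < j:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def build_pairs(pos, box, rlist, excl_indptr, excl_indices):
    """Non-excluded pairs (i<j) of all beads within ``rlist`` (minimum image)."""
    n = pos.shape[0]
    return build_pairs_subset(
        pos, np.arange(n, dtype=np.int64), box, rlist, excl_indptr, excl_indices
    )


@njit(cache=True, fastmath=True)
def build_pairs_subset(allpos, subset, box, rlist, excl_indptr, excl_indices):
    """Non-excluded pairs within ``rlist`` among the beads in ``subset``.

    Returned indices are global bead indices (int32, i < j).  Uses a
    half-stencil cell list when the box accommodates >= 3 cells per
    dimension, otherwise a brute-force loop.  Assumes box > 2*rlist in any
    dimension handled by the cell path.
    """
    n = subset.shape[0]
    pos = np.empty((n, 3))
    for t in range(n):
        for k in range(3):
            pos[t, k] = allpos[subset[t], k] % box[k]
    hb0 = 0.5 * box[0]
    hb1 = 0.5 * box[1]
    hb2 = 0.5 * box[2]
    ncx = int(box[0] // rlist)
    ncy = int(box[1] // rlist)
    ncz = int(box[2] // rlist)
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3 and n > 64

    r2max = rlist * rlist
    cap = 64 + n * 48
    pairs = np.empty((cap, 2), dtype=np.int32)
    m = 0
    if not use_cells:
        for i in range(n):
            gi = subset[i]
            for j in range(i + 1, n):
                d0 = pos[i, 0] - pos[j, 0]
                d1 = pos[i, 1] - pos[j, 1]
                d2 = pos[i, 2] - pos[j, 2]
                if d0 > hb0:
                    d0 -= box[0]
                elif d0 < -hb0:
                    d0 += box[0]
                if d1 > hb1:
                    d1 -= box[1]
                elif d1 < -hb1:
                    d1 += box[1]
                if d2 > hb2:
                    d2 -= box[2]
                elif d2 < -hb2:
                    d2 += box[2]
                r2 = d0 * d0 + d1 * d1 + d2 * d2
                if r2 < r2max and not _is_excluded(
                    gi, subset[j], excl_indptr, excl_indices
                ):
                    if m >= cap:
                        newcap = cap * 2
                        newp = np.empty((newcap, 2), dtype=np.int32)
                        newp[:m] = pairs[:m]
                        pairs = newp
                        cap = newcap
                    pairs[m, 0] = np.int32(gi)
                    pairs[m, 1] = np.int32(subset[j])
                    m += 1
        return pairs[:m].copy()

    # --- half-stencil cell list ---
    ncells = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncells, dtype=np.int64)
    for i in range(n):
        a = min(int(pos[i, 0] / box[0] * ncx), ncx - 1)
        b = min(int(pos[i, 1] / box[1] * ncy), ncy - 1)
        c = min(int(pos[i, 2] / box[2] * ncz), ncz - 1)
        cell_of[i] = (a * ncy + b) * ncz + c
        count[cell_of[i]] += 1
    indptr = np.zeros(ncells + 1, dtype=np.int64)
    for c in range(ncells):
        indptr[c + 1] = indptr[c] + count[c]
    fill = indptr[:-1].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        order[fill[cell_of[i]]] = i
        fill[cell_of[i]] += 1

    # 13 half-stencil neighbor offsets (dz>0, or dz=0 and dy>0, or
    # dz=dy=0 and dx>0)
    offsets = np.empty((13, 3), dtype=np.int64)
    t = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dz > 0 or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0):
                    offsets[t, 0] = dx
                    offsets[t, 1] = dy
                    offsets[t, 2] = dz
                    t += 1

    for a in range(ncx):
        for b in range(ncy):
            for c in range(ncz):
                cell = (a * ncy + b) * ncz + c
                lo = indptr[cell]
                hi = indptr[cell + 1]
                # in-cell pairs
                for u in range(lo, hi):
                    i = order[u]
                    for v in range(u + 1, hi):
                        j = order[v]
                        d0 = pos[i, 0] - pos[j, 0]
                        d1 = pos[i, 1] - pos[j, 1]
                        d2 = pos[i, 2] - pos[j, 2]
                        if d0 > hb0:
                            d0 -= box[0]
                        elif d0 < -hb0:
                            d0 += box[0]
                        if d1 > hb1:
                            d1 -= box[1]
                        elif d1 < -hb1:
                            d1 += box[1]
                        if d2 > hb2:
                            d2 -= box[2]
                        elif d2 < -hb2:
                            d2 += box[2]
                        r2 = d0 * d0 + d1 * d1 + d2 * d2
                        if r2 < r2max:
                            gi = subset[i]
                            gj = subset[j]
                            if gi > gj:
                                gi, gj = gj, gi
                            if not _is_excluded(gi, gj, excl_indptr, excl_indices):
                                if m >= cap:
                                    newcap = cap * 2
                                    newp = np.empty((newcap, 2), dtype=np.int32)
                                    newp[:m] = pairs[:m]
                                    pairs = newp
                                    cap = newcap
                                pairs[m, 0] = np.int32(gi)
                                pairs[m, 1] = np.int32(gj)
                                m += 1
                # cross-cell pairs over the half stencil
                for s_ in range(13):
                    aa = (a + offsets[s_, 0]) % ncx
                    bb = (b + offsets[s_, 1]) % ncy
                    cc = (c + offsets[s_, 2]) % ncz
                    other = (aa * ncy + bb) * ncz + cc
                    olo = indptr[other]
                    ohi = indptr[other + 1]
                    for u in range(lo, hi):
                        i = order[u]
                        for v in range(olo, ohi):
                            j = order[v]
                            d0 = pos[i, 0] - pos[j, 0]
                            d1 = pos[i, 1] - pos[j, 1]
                            d2 = pos[i, 2] - pos[j, 2]
                            if d0 > hb0:
                                d0 -= box[0]
                            elif d0 < -hb0:
                                d0 += box[0]
                            if d1 > hb1:
                                d1 -= box[1]
                            elif d1 < -hb1:
                                d1 += box[1]
                            if d2 > hb2:
                                d2 -= box[2]
                            elif d2 < -hb2:
                                d2 += box[2]
                            r2 = d0 * d0 + d1 * d1 + d2 * d2
                            if r2 < r2max:
                                gi = subset[i]
                                gj = subset[j]
                                if gi > gj:
                                    gi, gj = gj, gi
                                if not _is_excluded(gi, gj, excl_indptr, excl_indices):
                                    if m >= cap:
                                        newcap = cap * 2
                                        newp = np.empty((newcap, 2), dtype=np.int32)
                                        newp[:m] = pairs[:m]
                                        pairs = newp
                                        cap = newcap
                                    pairs[m, 0] = np.int32(gi)
                                    pairs[m, 1] = np.int32(gj)
                                    m += 1
    return pairs[:m].copy()


@njit(cache=True)
def pairs_to_csr(pairs, sigma, lam, n):
    """Row-major (CSR) neighbor structure with precomputed pair parameters.

    Grouping pairs by their lower bead index lets the force loop keep that
    bead's accumulator in registers; (sigma_bar^2, lambda_bar) are
    precomputed per pair.
    """
    m = pairs.shape[0]
    count = np.zeros(n + 1, dtype=np.int64)
    for p in range(m):
        count[pairs[p, 0] + 1] += 1
    for i in range(n):
        count[i + 1] += count[i]
    indptr = count
    jcol = np.empty(m, dtype=np.int32)
    sb2 = np.empty(m)
    lb = np.empty(m)
    fill = indptr[:-1].copy()
    for p in range(m):
        i = pairs[p, 0]
        j = pairs[p, 1]
        t = fill[i]
        fill[i] = t + 1
        jcol[t] = j
        sb = 0.5 * (sigma[i] + sigma[j])
        sb2[t] = sb * sb
        lb[t] = 0.5 * (lam[i] + lam[j])
    return indptr, jcol, sb2, lb


@njit(cache=True, fastmath=True)
def energy_forces(
    pos,
    box,
    lj_indptr,
    lj_jcol,
    lj_sb2,
    lj_lb,
    coul_pairs,
    charge,
    epsilon,
    lj_cut,
    debye_len,
    dielectric,
    coul_cut,
    bonds,
    bond_r0,
    bond_k,
):
    """Total potential energy and forces.

    ``lj_pairs`` is the neighbor list for the hydropathy-scaled short-range
    term (all beads); ``coul_pairs`` the (typically much shorter) list of
    charged-bead pairs for screened electrostatics.  Returns ``(energy,
    forces, min_r, min_i, min_j)`` where ``min_r`` is the smallest
    short-range pair distance seen (for overlap diagnostics).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    min_r = 1.0e30
    min_i = -1
    min_j = -1
    coulk = 138.935458  # e^2/(4 pi eps0), kJ nm / mol
    ib0 = 1.0 / box[0]
    ib1 = 1.0 / box[1]
    ib2 = 1.0 / box[2]
    lj_cut2 = lj_cut * lj_cut
    coul_cut2 = coul_cut * coul_cut
    crossover = 1.2599210498948732  # 2^(1/3): r2 <= crossover * sbar^2

    for i in range(n):
        lo = lj_indptr[i]
        hi = lj_indptr[i + 1]
        if lo == hi:
            continue
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        fxi = 0.0
        fyi = 0.0
        fzi = 0.0
        for t in range(lo, hi):
            j = lj_jcol[t]
            d0 = xi - pos[j, 0]
            d1 = yi - pos[j, 1]
            d2 = zi - pos[j, 2]
            d0 -= box[0] * np.rint(d0 * ib0)
            d1 -= box[1] * np.rint(d1 * ib1)
            d2 -= box[2] * np.rint(d2 * ib2)
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 >= lj_cut2:
                continue
            if r2 < min_r:
                min_r = r2
                min_i = i
                min_j = j
            s2 = lj_sb2[t]
            lbar = lj_lb[t]
            inv_r2 = 1.0 / r2
            sr2 = s2 * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            phi = 4.0 * epsilon * (sr12 - sr6)
            dphi_r = -24.0 * epsilon * (2.0 * sr12 - sr6) * inv_r2  # (dphi/dr)/r
            if r2 <= s2 * crossover:
                energy += phi + (1.0 - lbar) * epsilon
                f = -dphi_r
            else:
                energy += lbar * phi
                f = -lbar * dphi_r
            fx = f * d0
            fy = f * d1
            fz = f * d2
            fxi += fx
            fyi += fy
            fzi += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
        forces[i, 0] += fxi
        forces[i, 1] += fyi
        forces[i, 2] += fzi
    min_r = np.sqrt(min_r) if min_i >= 0 else 1.0e30

    for p in range(coul_pairs.shape[0]):
        i = coul_pairs[p, 0]
        j = coul_pairs[p, 1]
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        d0 -= box[0] * np.rint(d0 * ib0)
        d1 -= box[1] * np.rint(d1 * ib1)
        d2 -= box[2] * np.rint(d2 * ib2)
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= coul_cut2:
            continue
        r = np.sqrt(r2)
        u = coulk * charge[i] * charge[j] * np.exp(-r / debye_len) / (dielectric * r)
        energy += u
        f = u * (1.0 / r + 1.0 / debye_len) / r
        fx = f * d0
        fy = f * d1
        fz = f * d2
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        d0 -= box[0] * np.rint(d0 / box[0])
        d1 -= box[1] * np.rint(d1 / box[1])
        d2 -= box[2] * np.rint(d2 / box[2])
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        dr = r - bond_r0
        energy += 0.5 * bond_k * dr * dr
        fmag = -bond_k * dr
        fx = fmag * d0 / r
        fy = fmag * d1 / r
        fz = fmag * d2 / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    return energy, forces, min_r, min_i, min_j


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention; q maps body frame -> lab frame)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _qmul(a, b):
    out = np.empty(4)
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
    return out


@njit(cache=True, inline="always")
def _qrotmat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1 - 2 * (y * y + z * z)
    R[0, 1] = 2 * (x * y - w * z)
    R[0, 2] = 2 * (x * z + w * y)
    R[1, 0] = 2 * (x * y + w * z)
    R[1, 1] = 1 - 2 * (x * x + z * z)
    R[1, 2] = 2 * (y * z - w * x)
    R[2, 0] = 2 * (x * z - w * y)
    R[2, 1] = 2 * (y * z + w * x)
    R[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True)
def _free_axis(q, L, inertia, axis, dt):
    """Exact evolution under the single-axis Hamiltonian L_axis^2 / (2 I_axis)."""
    phi = dt * L[axis] / inertia[axis]
    half = 0.5 * phi
    rot = np.zeros(4)
    rot[0] = np.cos(half)
    rot[1 + axis] = np.sin(half)
    qn = _qmul(q, rot)
    for k in range(4):
        q[k] = qn[k]
    # body-frame L precesses by -phi about the axis
    c = np.cos(phi)
    s = np.sin(phi)
    a1 = (axis + 1) % 3
    a2 = (axis + 2) % 3
    l1 = L[a1]
    l2 = L[a2]
    L[a1] = c * l1 + s * l2
    L[a2] = -s * l1 + c * l2


@njit(cache=True)
def _free_rotor(q, L, inertia, dt):
    _free_axis(q, L, inertia, 2, 0.5 * dt)
    _free_axis(q, L, inertia, 1, 0.5 * dt)
    _free_axis(q, L, inertia, 0, dt)
    _free_axis(q, L, inertia, 1, 0.5 * dt)
    _free_axis(q, L, inertia, 2, 0.5 * dt)


@njit(cache=True)
def rigid_positions(com, quat, grp_indptr, grp_members, body_coords, pos):
    """Overwrite member bead positions from rigid-group COM + orientation."""
    R = np.empty((3, 3))
    for g in range(com.shape[0]):
        _qrotmat(quat[g], R)
        for t in range(grp_indptr[g], grp_indptr[g + 1]):
            i = grp_members[t]
            b = body_coords[t]
            for k in range(3):
                pos[i, k] = (
                    com[g, k] + R[k, 0] * b[0] + R[k, 1] * b[1] + R[k, 2] * b[2]
                )


@njit(cache=True)
def _reduce_rigid_forces(
    forces, pos, com, quat, grp_indptr, grp_members, fnet, torque_body
):
    R = np.empty((3, 3))
    for g in range(com.shape[0]):
        _qrotmat(quat[g], R)
        for k in range(3):
            fnet[g, k] = 0.0
            torque_body[g, k] = 0.0
        tl0 = 0.0
        tl1 = 0.0
        tl2 = 0.0
        for t in range(grp_indptr[g], grp_indptr[g + 1]):
            i = grp_members[t]
            fx, fy, fz = forces[i, 0], forces[i, 1], forces[i, 2]
            rx = pos[i, 0] - com[g, 0]
            ry = pos[i, 1] - com[g, 1]
            rz = pos[i, 2] - com[g, 2]
            fnet[g, 0] += fx
            fnet[g, 1] += fy
            fnet[g, 2] += fz
            tl0 += ry * fz - rz * fy
            tl1 += rz * fx - rx * fz
            tl2 += rx * fy - ry * fx
        # lab -> body: R^T
        torque_body[g, 0] = R[0, 0] * tl0 + R[1, 0] * tl1 + R[2, 0] * tl2
        torque_body[g, 1] = R[0, 1] * tl0 + R[1, 1] * tl1 + R[2, 1] * tl2
        torque_body[g, 2] = R[0, 2] * tl0 + R[1, 2] * tl1 + R[2, 2] * tl2


@njit(cache=True)
def run_chunk(
    # mutable state
    pos,
    vel,
    com,
    quat,
    vcom,
    lbody,
    # topology / parameters
    flex_idx,
    charged_idx,
    masses,
    grp_indptr,
    grp_members,
    body_coords,
    grp_mass,
    grp_inertia,
    box,
    sigma,
    lam,
    charge,
    epsilon,
    lj_cut,
    debye_len,
    dielectric,
    coul_cut,
    bonds,
    bond_r0,
    bond_k,
    excl_indptr,
    excl_indices,
    # integration controls
    dt,
    ou_c,  # exp(-dt/tau); thermostat off when < 0
    kt,
    noise,  # (n_steps, n_dof_rows, 3) standard normals (unused if ou_c < 0)
    skin,
    n_steps,
):
    """Advance ``n_steps`` BAOAB Langevin (or NVE velocity-Verlet) steps.

    ``noise`` rows are laid out as [flexible beads | group COM | group
    rotation].  Returns ``(status, step, energy, i, j)``; status 0 is
    success, 1 a fatal overlap, 2 a displacement blow-up.
    """
    n_flex = flex_idx.shape[0]
    n_grp = com.shape[0]
    nvt = ou_c >= 0.0
    sq = np.sqrt(max(0.0, 1.0 - ou_c * ou_c)) if nvt else 0.0
    rlist_lj = lj_cut + skin
    rlist_coul = coul_cut + skin

    pairs = build_pairs(pos, box, rlist_lj, excl_indptr, excl_indices)
    indptr, jcol, sb2, lb = pairs_to_csr(pairs, sigma, lam, pos.shape[0])
    cpairs = build_pairs_subset(
        pos, charged_idx, box, rlist_coul, excl_indptr, excl_indices
    )
    ref_pos = pos.copy()
    energy, forces, min_r, mi, mj = energy_forces(
        pos, box, indptr, jcol, sb2, lb, cpairs, charge, epsilon, lj_cut,
        debye_len, dielectric, coul_cut, bonds, bond_r0, bond_k,
    )
    if min_r < OVERLAP_R:
        return 1, 0, energy, mi, mj
    fnet = np.zeros((n_grp, 3))
    tq = np.zeros((n_grp, 3))
    if n_grp > 0:
        _reduce_rigid_forces(forces, pos, com, quat, grp_indptr, grp_members, fnet, tq)

    half = 0.5 * dt
    for step in range(n_steps):
        prev = pos.copy()
        # B
        for t in range(n_flex):
            i = flex_idx[t]
            for k in range(3):
                vel[i, k] += half * forces[i, k] / masses[i]
        for g in range(n_grp):
            for k in range(3):
                vcom[g, k] += half * fnet[g, k] / grp_mass[g]
                lbody[g, k] += half * tq[g, k]
        # A (dt/2)
        for t in range(n_flex):
            i = flex_idx[t]
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        for g in range(n_grp):
            for k in range(3):
                com[g, k] += half * vcom[g, k]
            _free_rotor(quat[g], lbody[g], grp_inertia[g], half)
        # O
        if nvt:
            for t in range(n_flex):
                i = flex_idx[t]
                amp = sq * np.sqrt(kt / masses[i])
                for k in range(3):
                    vel[i, k] = ou_c * vel[i, k] + amp * noise[step, t, k]
            for g in range(n_grp):
                ampv = sq * np.sqrt(kt / grp_mass[g])
                for k in range(3):
                    vcom[g, k] = ou_c * vcom[g, k] + ampv * noise[step, n_flex + g, k]
                for k in range(3):
                    ampl = sq * np.sqrt(kt * grp_inertia[g, k])
                    lbody[g, k] = (
                        ou_c * lbody[g, k]
                        + ampl * noise[step, n_flex + n_grp + g, k]
                    )
        # A (dt/2)
        for t in range(n_flex):
            i = flex_idx[t]
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        for g in range(n_grp):
            for k in range(3):
                com[g, k] += half * vcom[g, k]
            _free_rotor(quat[g], lbody[g], grp_inertia[g], half)
        if n_grp > 0:
            rigid_positions(com, quat, grp_indptr, grp_members, body_coords, pos)

        # instability check
        for i in range(pos.shape[0]):
            d0 = pos[i, 0] - prev[i, 0]
            d1 = pos[i, 1] - prev[i, 1]
            d2 = pos[i, 2] - prev[i, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 > MAX_STEP_DISP * MAX_STEP_DISP:
                return 2, step, energy, i, -1

        # neighbor-list refresh when anything moved more than skin/2
        maxd2 = 0.0
        for i in range(pos.shape[0]):
            d0 = pos[i, 0] - ref_pos[i, 0]
            d1 = pos[i, 1] - ref_pos[i, 1]
            d2 = pos[i, 2] - ref_pos[i, 2]
            d2s = d0 * d0 + d1 * d1 + d2 * d2
            if d2s > maxd2:
                maxd2 = d2s
        if maxd2 > 0.25 * skin * skin:
            pairs = build_pairs(pos, box, rlist_lj, excl_indptr, excl_indices)
            indptr, jcol, sb2, lb = pairs_to_csr(pairs, sigma, lam, pos.shape[0])
            cpairs = build_pairs_subset(
                pos, charged_idx, box, rlist_coul, excl_indptr, excl_indices
            )
            ref_pos = pos.copy()

        energy, forces, min_r, mi, mj = energy_forces(
            pos, box, indptr, jcol, sb2, lb, cpairs, charge, epsilon, lj_cut,
            debye_len, dielectric, coul_cut, bonds, bond_r0, bond_k,
        )
        if min_r < OVERLAP_R:
            return 1, step, energy, mi, mj
        if n_grp > 0:
            _reduce_rigid_forces(
                forces, pos, com, quat, grp_indptr, grp_members, fnet, tq
            )
        # B
        for t in range(n_flex):
            i = flex_idx[t]
            for k in range(3):
                vel[i, k] += half * forces[i, k] / masses[i]
        for g in range(n_grp):
            for k in range(3):
                vcom[g, k] += half * fnet[g, k] / grp_mass[g]
                lbody[g, k] += half * tq[g, k]

    return 0, n_steps, energy, -1, -1
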