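"""Numba-jitted inner loops: neighbor search, forces, virial, Langevin steps.

All kernels operate on plain float64/int64 arrays unpacked from the
containers in :mod:`condrheo.system`.  The scalar reference forms live in
:mod:`condrheo.potentials`; the test suite asserts force = -grad U and
kernel-vs-brute-force equivalence.

Status codes returned by the run kernel:
  0 ok, 1 FENE overstretch, 2 non-finite coordinates, 3 pair-buffer overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_NONFINITE = 2
STATUS_OVERFLOW = 3

PAIR_LJ = 0
PAIR_HPS = 1
PAIR_SOFT = 2

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _rint(x):
    return np.floor(x + 0.5)


@njit(cache=True, inline="always")
def _min_image(dx, dy, dz, lx, ly, lz, tilt, px, py, pz):
    if pz:
        dz -= lz * _rint(dz / lz)
    if py:
        ny = _rint(dy / ly)
        dy -= ly * ny
        dx -= tilt * ny
    if px:
        dx -= lx * _rint(dx / lx)
    return dx, dy, dz


@njit(cache=True)
def build_pairs_bruteforce(
    pos, lx, ly, lz, tilt, px, py, pz, cutoff, pairs_i, pairs_j
):
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cap = pairs_i.shape[0]
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, tilt, px, py, pz)
            if dx * dx + dy * dy + dz * dz < c2:
                if m >= cap:
                    return -1
                pairs_i[m] = i
                pairs_j[m] = j
                m += 1
    return m


@njit(cache=True)
def build_pairs_cells(
    pos, lx, ly, lz, tilt, px, py, pz, cutoff, xw, pairs_i, pairs_j
):
    """Cell-list pair build; falls back to brute force for small boxes.

    ``xw`` is the x-stencil half width (2 when a tilt can be present, else 1).
    """
    n = pos.shape[0]
    ncx = int(lx / cutoff)
    ncy = int(ly / cutoff)
    ncz = int(lz / cutoff)
    if ncx < 2 * xw + 1 or ncy < 3 or ncz < 3 or n < 32:
        return build_pairs_bruteforce(
            pos, lx, ly, lz, tilt, px, py, pz, cutoff, pairs_i, pairs_j
        )
    ncells = ncx * ncy * ncz
    # fractional coordinates (remove tilt from x so cells tile the sheared box)
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cellof = np.empty(n, dtype=np.int64)
    for i in range(n):
        sy = pos[i, 1] / ly
        sx = (pos[i, 0] - tilt * sy) / lx
        sz = pos[i, 2] / lz
        sx -= np.floor(sx)
        sy -= np.floor(sy)
        sz -= np.floor(sz)
        cx = int(sx * ncx)
        cy = int(sy * ncy)
        cz = int(sz * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cz * ncy + cy) * ncx + cx
        cellof[i] = c
        nxt[i] = head[c]
        head[c] = i

    c2 = cutoff * cutoff
    cap = pairs_i.shape[0]
    m = 0
    for i in range(n):
        ci = cellof[i]
        cx = ci % ncx
        cy = (ci // ncx) % ncy
        cz = ci // (ncx * ncy)
        for dcz in range(-1, 2):
            z = cz + dcz
            if pz:
                z = z % ncz
            elif z < 0 or z >= ncz:
                continue
            for dcy in range(-1, 2):
                y = cy + dcy
                if py:
                    y = y % ncy
                elif y < 0 or y >= ncy:
                    continue
                for dcx in range(-xw, xw + 1):
                    x = cx + dcx
                    if px:
                        x = x % ncx
                    elif x < 0 or x >= ncx:
                        continue
                    c = (z * ncy + y) * ncx + x
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz_ = pos[i, 2] - pos[j, 2]
                            dx, dy, dz_ = _min_image(
                                dx, dy, dz_, lx, ly, lz, tilt, px, py, pz
                            )
                            if dx * dx + dy * dy + dz_ * dz_ < c2:
                                if m >= cap:
                                    return -1
                                pairs_i[m] = i
                                pairs_j[m] = j
                                m += 1
                        j = nxt[j]
    return m


@njit(cache=True, inline="always")
def _pair_uf(r2, eps, sig, rc, shifted, style, lam, soft_a):
    """Pair energy and force-over-r at squared distance r2.  r2 <= rc^2."""
    r = np.sqrt(r2)
    if style == PAIR_SOFT:
        arg = np.pi * r / rc
        u = soft_a * (1.0 + np.cos(arg))
        fr = soft_a * np.pi / rc * np.sin(arg) / r
        return u, fr
    sr2 = sig * sig / r2
    sr6 = sr2 * sr2 * sr2
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
    if style == PAIR_HPS:
        src2 = sig * sig / (rc * rc)
        src6 = src2 * src2 * src2
        u_rc = 4.0 * eps * (src6 * src6 - src6)
        if r <= _SIXTH_ROOT_2 * sig:
            u = u + (1.0 - lam) * eps - lam * u_rc
        else:
            u = lam * (u - u_rc)
            fr = lam * fr
        return u, fr
    # plain truncation is energy-shifted so the bookkeeping energy is
    # continuous at rc (forces unchanged); shifted_force also zeroes the force
    src2 = sig * sig / (rc * rc)
    src6 = src2 * src2 * src2
    u_rc = 4.0 * eps * (src6 * src6 - src6)
    if shifted:
        f_rc = 24.0 * eps * (2.0 * src6 * src6 - src6) / rc
        u = u - u_rc + (r - rc) * f_rc
        fr = fr - f_rc / r
    else:
        u = u - u_rc
    return u, fr


@njit(cache=True, inline="always")
def _is_excluded(key, excl):
    lo = 0
    hi = excl.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if excl[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl.shape[0] and excl[lo] == key


@njit(cache=True)
def compute_forces(
    pos,
    type_id,
    pairs_i,
    pairs_j,
    npairs,
    excl,
    eps,
    sig,
    rc,
    shifted,
    style,
    lam,
    soft_a,
    bonds,
    bond_kind,
    fene_k,
    fene_r0,
    harm_k,
    harm_r0,
    angles,
    angle_k,
    angle_t0,
    lx,
    ly,
    lz,
    tilt,
    px,
    py,
    pz,
    forces,
    virial,
):
    """Fill ``forces`` (N,3) and ``virial`` (6: xx,yy,zz,xy,xz,yz).

    Returns (potential_energy, error_bond_index); error index -1 means ok,
    otherwise the offending FENE bond index.
    """
    forces[:] = 0.0
    virial[:] = 0.0
    pe = 0.0
    n = pos.shape[0]
    has_excl = excl.shape[0] > 0
    # nonbonded
    for p in range(npairs):
        i = pairs_i[p]
        j = pairs_j[p]
        if has_excl and _is_excluded(i * n + j, excl):
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, tilt, px, py, pz)
        r2 = dx * dx + dy * dy + dz * dz
        ti = type_id[i]
        tj = type_id[j]
        rcij = rc[ti, tj]
        if r2 < rcij * rcij:
            u, fr = _pair_uf(
                r2, eps[ti, tj], sig[ti, tj], rcij, shifted, style, lam[ti, tj], soft_a
            )
            pe += u
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0] += dx * fx
            virial[1] += dy * fy
            virial[2] += dz * fz
            virial[3] += dx * fy
            virial[4] += dx * fz
            virial[5] += dy * fz
    # bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, tilt, px, py, pz)
        r2 = dx * dx + dy * dy + dz * dz
        if bond_kind[b] == 0:  # FENE
            x = r2 / (fene_r0 * fene_r0)
            if x >= 1.0:
                return pe, b
            pe += -0.5 * fene_k * fene_r0 * fene_r0 * np.log(1.0 - x)
            fr = -fene_k / (1.0 - x)  # attractive: force/r on i along -d
        else:  # harmonic
            r = np.sqrt(r2)
            d = r - harm_r0
            pe += harm_k * d * d
            fr = -2.0 * harm_k * d / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
        virial[3] += dx * fy
        virial[4] += dx * fz
        virial[5] += dy * fz
    # angles (j central)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ax, ay, az = _min_image(ax, ay, az, lx, ly, lz, tilt, px, py, pz)
        bx, by, bz = _min_image(bx, by, bz, lx, ly, lz, tilt, px, py, pz)
        la2 = ax * ax + ay * ay + az * az
        lb2 = bx * bx + by * by + bz * bz
        la = np.sqrt(la2)
        lb = np.sqrt(lb2)
        c = (ax * bx + ay * by + az * bz) / (la * lb)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            s2 = 1e-16
        s = np.sqrt(s2)
        theta = np.arccos(c)
        dth = theta - angle_t0[a]
        pe += angle_k[a] * dth * dth
        coef = 2.0 * angle_k[a] * dth / s
        fix = coef * (bx / (la * lb) - c * ax / la2)
        fiy = coef * (by / (la * lb) - c * ay / la2)
        fiz = coef * (bz / (la * lb) - c * az / la2)
        fkx = coef * (ax / (la * lb) - c * bx / lb2)
        fky = coef * (ay / (la * lb) - c * by / lb2)
        fkz = coef * (az / (la * lb) - c * bz / lb2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial[0] += ax * fix + bx * fkx
        virial[1] += ay * fiy + by * fky
        virial[2] += az * fiz + bz * fkz
        virial[3] += ax * fiy + bx * fky
        virial[4] += ax * fiz + bx * fkz
        virial[5] += ay * fiz + by * fkz
    return pe, -1


@njit(cache=True)
def _wrap_positions(pos, vel, images, lx, ly, lz, tilt, px, py, pz, rate):
    for i in range(pos.shape[0]):
        if py:
            ny = np.floor(pos[i, 1] / ly)
            if ny != 0.0:
                pos[i, 1] -= ny * ly
                pos[i, 0] -= ny * tilt
                vel[i, 0] -= ny * rate * ly
                images[i, 1] += np.int64(ny)
        if px:
            nx = np.floor(pos[i, 0] / lx)
            if nx != 0.0:
                pos[i, 0] -= nx * lx
                images[i, 0] += np.int64(nx)
        if pz:
            nz = np.floor(pos[i, 2] / lz)
            if nz != 0.0:
                pos[i, 2] -= nz * lz
                images[i, 2] += np.int64(nz)


@njit(cache=True)
def run_langevin(
    pos,
    vel,
    images,
    type_id,
    mass,
    excl,
    bonds,
    bond_kind,
    fene_k,
    fene_r0,
    harm_k,
    harm_r0,
    angles,
    angle_k,
    angle_t0,
    eps,
    sig,
    rc,
    shifted,
    style,
    lam,
    soft_a,
    lx,
    ly,
    lz,
    tilt_in,
    px,
    py,
    pz,
    wall_lo,
    wall_hi,
    has_walls,
    dt,
    n_steps,
    temp,
    gamma_l,
    seed,
    gamma0,
    omega,
    t_start,
    sample_stride,
    out,
    skin,
    pairs_i,
    pairs_j,
):
    """BAOAB Langevin integration with optional oscillatory Lees-Edwards shear.

    ``out`` rows: (t, strain, sxx, syy, szz, sxy, sxz, syz, T_kin, pe).
    Returns (status, final_tilt, n_samples, bad_index).
    """
    n = pos.shape[0]
    np.random.seed(seed)
    volume = lx * ly * lz
    if has_walls:
        volume = (wall_hi - wall_lo) * ly * lz
    rc_max = 0.0
    for i in range(rc.shape[0]):
        for j in range(rc.shape[1]):
            if rc[i, j] > rc_max:
                rc_max = rc[i, j]
    cutoff = rc_max + skin
    xw = 2 if (py and (gamma0 != 0.0 or tilt_in != 0.0)) else 1

    tilt = tilt_in
    shearing = gamma0 != 0.0
    gamma_prev = gamma0 * np.sin(omega * t_start)

    forces = np.zeros((n, 3))
    virial = np.zeros(6)
    pos_ref = pos.copy()
    tilt_ref = tilt

    npairs = build_pairs_cells(
        pos, lx, ly, lz, tilt, px, py, pz, cutoff, xw, pairs_i, pairs_j
    )
    if npairs < 0:
        return STATUS_OVERFLOW, tilt, 0, -1
    pe, err = compute_forces(
        pos, type_id, pairs_i, pairs_j, npairs, excl, eps, sig, rc, shifted, style,
        lam, soft_a, bonds, bond_kind, fene_k, fene_r0, harm_k, harm_r0, angles,
        angle_k, angle_t0, lx, ly, lz, tilt, px, py, pz, forces, virial,
    )
    if err >= 0:
        return STATUS_OVERSTRETCH, tilt, 0, err

    c1 = np.exp(-gamma_l * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temp / mass)
    half = 0.5 * dt
    nsamp = 0

    for step in range(n_steps):
        t = t_start + step * dt
        rate = 0.0
        if shearing:
            gamma_t = gamma0 * np.sin(omega * t)
            dgam = gamma_t - gamma_prev
            gamma_prev = gamma_t
            if dgam != 0.0:
                for i in range(n):
                    pos[i, 0] += dgam * pos[i, 1]
                tilt += dgam * ly
                tilt -= lx * _rint(tilt / lx)
            rate = gamma0 * omega * np.cos(omega * (t + half))
        # B
        inv_m = 1.0 / mass
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            vel[i, 2] += half * forces[i, 2] * inv_m
        # A
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # O (on peculiar velocities)
        if gamma_l > 0.0:
            for i in range(n):
                vpx = vel[i, 0] - rate * pos[i, 1]
                vpx = c1 * vpx + c2 * np.random.normal(0.0, 1.0)
                vel[i, 0] = vpx + rate * pos[i, 1]
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal(0.0, 1.0)
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal(0.0, 1.0)
        # A
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if has_walls:
            for i in range(n):
                if pos[i, 0] < wall_lo:
                    pos[i, 0] = 2.0 * wall_lo - pos[i, 0]
                    vel[i, 0] = -vel[i, 0]
                elif pos[i, 0] > wall_hi:
                    pos[i, 0] = 2.0 * wall_hi - pos[i, 0]
                    vel[i, 0] = -vel[i, 0]
        _wrap_positions(pos, vel, images, lx, ly, lz, tilt, px, py, pz, rate)
        # neighbor rebuild check
        maxd2 = 0.0
        for i in range(n):
            ddx = pos[i, 0] - pos_ref[i, 0]
            ddy = pos[i, 1] - pos_ref[i, 1]
            ddz = pos[i, 2] - pos_ref[i, 2]
            ddx, ddy, ddz = _min_image(ddx, ddy, ddz, lx, ly, lz, tilt, px, py, pz)
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > maxd2:
                maxd2 = d2
        drift = np.sqrt(maxd2) + np.abs(tilt - tilt_ref)
        if drift > 0.5 * skin:
            npairs = build_pairs_cells(
                pos, lx, ly, lz, tilt, px, py, pz, cutoff, xw, pairs_i, pairs_j
            )
            if npairs < 0:
                return STATUS_OVERFLOW, tilt, nsamp, step
            pos_ref[:] = pos
            tilt_ref = tilt
        pe, err = compute_forces(
            pos, type_id, pairs_i, pairs_j, npairs, excl, eps, sig, rc, shifted,
            style, lam, soft_a, bonds, bond_kind, fene_k, fene_r0, harm_k,
            harm_r0, angles, angle_k, angle_t0, lx, ly, lz, tilt, px, py, pz,
            forces, virial,
        )
        if err >= 0:
            return STATUS_OVERSTRETCH, tilt, nsamp, err
        # B
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            vel[i, 2] += half * forces[i, 2] * inv_m
        if not np.isfinite(pos[0, 0]) or not np.isfinite(vel[0, 0]):
            return STATUS_NONFINITE, tilt, nsamp, step
        if sample_stride > 0 and (step + 1) % sample_stride == 0:
            kxx = 0.0
            kyy = 0.0
            kzz = 0.0
            kxy = 0.0
            kxz = 0.0
            kyz = 0.0
            for i in range(n):
                vx = vel[i, 0] - rate * pos[i, 1]
                vy = vel[i, 1]
                vz = vel[i, 2]
                kxx += mass * vx * vx
                kyy += mass * vy * vy
                kzz += mass * vz * vz
                kxy += mass * vx * vy
                kxz += mass * vx * vz
                kyz += mass * vy * vz
            tnow = t + dt
            out[nsamp, 0] = tnow
            out[nsamp, 1] = gamma0 * np.sin(omega * tnow) if shearing else 0.0
            out[nsamp, 2] = (kxx + virial[0]) / volume
            out[nsamp, 3] = (kyy + virial[1]) / volume
            out[nsamp, 4] = (kzz + virial[2]) / volume
            # off-diagonals in the material (tension-positive) convention
            out[nsamp, 5] = -(kxy + virial[3]) / volume
            out[nsamp, 6] = -(kxz + virial[4]) / volume
            out[nsamp, 7] = -(kyz + virial[5]) / volume
            out[nsamp, 8] = (kxx + kyy + kzz) / (3.0 * n)
            out[nsamp, 9] = pe
            nsamp += 1
    return STATUS_OK, tilt, nsamp, -1


@njit(cache=True)
def min_pair_distance(pos, lx, ly, lz, tilt, px, py, pz, cutoff, pairs_i, pairs_j):
    """Smallest nonbonded pair distance below ``cutoff`` (inf if none)."""
    xw = 2 if tilt != 0.0 else 1
    m = build_pairs_cells(pos, lx, ly, lz, tilt, px, py, pz, cutoff, xw, pairs_i, pairs_j)
    best = np.inf
    for p in range(m):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, lx, ly, lz, tilt, px, py, pz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < best:
            best = r2
    return np.sqrt(best)
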