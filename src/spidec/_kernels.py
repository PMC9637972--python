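"""Numba-compiled kernels behind the MD and MC engines.

These functions operate on plain arrays only. Pair interactions are encoded
per type pair with mode codes (0 plain LJ, 1 cut-shifted, 2 force-shifted,
3 WCA) plus precomputed energy/force shift constants. The scalar reference
implementations in :mod:`spidec.potentials` are the tested ground truth for
everything here.

The random stream is numba's internal NumPy-compatible generator, seeded once
per run via :func:`seed_rng`; a run is bitwise deterministic for a given seed
on a fixed platform.
"""

import numpy as np
from numba import njit

MODE_PLAIN = 0
MODE_CUT_SHIFTED = 1
MODE_FORCE_SHIFTED = 2
MODE_WCA = 3

# hard-core overlap sentinel: finite so fastmath-compiled kernels handle it
OVERLAP = 1e30


@njit(cache=True, error_model="numpy")
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always", error_model="numpy", fastmath=True)
def _min_image(d, L):
    # positions are kept wrapped in [0, L), so |d| < L and one branchy
    # correction suffices (much cheaper than a floor per component)
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always", error_model="numpy", fastmath=True)
def _pair_eg(r2, eps, sig, rc, mode, ushift, fshift):
    """Energy and g = -U'(r)/r for one nonbonded pair at squared distance r2.

    The force on particle j (with dr = r_j - r_i) is g * dr.
    """
    if mode == MODE_WCA:
        cut = 1.122462048309373 * sig
        if r2 >= cut * cut:
            return 0.0, 0.0
        sr2 = sig * sig / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        u = 4.0 * eps * (sr12 - sr6) + eps
        g = 24.0 * eps * (2.0 * sr12 - sr6) / r2
        return u, g
    if mode != MODE_PLAIN and r2 >= rc * rc:
        return 0.0, 0.0
    sr2 = sig * sig / r2
    sr6 = sr2 * sr2 * sr2
    sr12 = sr6 * sr6
    u = 4.0 * eps * (sr12 - sr6)
    g = 24.0 * eps * (2.0 * sr12 - sr6) / r2
    if mode == MODE_CUT_SHIFTED:
        u -= ushift
    elif mode == MODE_FORCE_SHIFTED:
        r = np.sqrt(r2)
        u = u - ushift + fshift * (r - rc)
        g = g - fshift / r
    return u, g


@njit(cache=True, error_model="numpy", fastmath=True)
def build_pairs(pos, box, cut, pairs):
    """Enumerate each pair within ``cut`` exactly once into ``pairs``.

    Uses a linked-cell grid when at least 3 cells fit per axis, otherwise an
    all-pairs sweep with the minimum image. Returns the number of pairs, or
    -1 if ``pairs`` overflowed.
    """
    n = pos.shape[0]
    cut2 = cut * cut
    cap = pairs.shape[0]
    # cells no smaller than the cutoff; cap the grid so binning stays O(n)
    max_dim = int(np.cbrt(8.0 * n)) + 1
    ncx = min(int(box[0] / cut), max(3, max_dim))
    ncy = min(int(box[1] / cut), max(3, max_dim))
    ncz = min(int(box[2] / cut), max(3, max_dim))
    npair = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
                dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
                dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
                if dx * dx + dy * dy + dz * dz < cut2:
                    if npair >= cap:
                        return -1
                    pairs[npair, 0] = i
                    pairs[npair, 1] = j
                    npair += 1
        return npair

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    cix = np.empty(n, dtype=np.int32)
    ciy = np.empty(n, dtype=np.int32)
    ciz = np.empty(n, dtype=np.int32)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        cix[i] = cx
        ciy[i] = cy
        ciz[i] = cz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    # half set of 13 neighbor offsets + same cell
    offs = np.array(
        [
            [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
            [0, 1, 1], [0, 1, -1],
            [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
        ],
        dtype=np.int32,
    )
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                # same cell
                i = head[c]
                while i != -1:
                    j = nxt[i]
                    while j != -1:
                        dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
                        dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
                        dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if npair >= cap:
                                return -1
                            pairs[npair, 0] = i
                            pairs[npair, 1] = j
                            npair += 1
                        j = nxt[j]
                    i = nxt[i]
                # neighbor cells
                for k in range(13):
                    cx2 = (cx + offs[k, 0]) % ncx
                    cy2 = (cy + offs[k, 1]) % ncy
                    cz2 = (cz + offs[k, 2]) % ncz
                    c2 = (cx2 * ncy + cy2) * ncz + cz2
                    i = head[c]
                    while i != -1:
                        j = head[c2]
                        while j != -1:
                            dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
                            dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
                            dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if npair >= cap:
                                    return -1
                                pairs[npair, 0] = i
                                pairs[npair, 1] = j
                                npair += 1
                            j = nxt[j]
                        i = nxt[i]
    return npair


@njit(cache=True, error_model="numpy", fastmath=True)
def compute_forces(
    pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    bonds, bond_k, bond_r0, mol, exclude_adjacent,
    pairs, n_pairs, forces,
):
    """Forces, potential energy and diagonal virial from a prebuilt pair list.

    Adjacent beads of the same chain are excluded from the nonbonded loop when
    ``exclude_adjacent`` is set; bonded terms are added from ``bonds``.
    Returns (pe, vxx, vyy, vzz) where v_aa = sum over pairs of r_a * f_a.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    vxx = 0.0
    vyy = 0.0
    vzz = 0.0
    for k in range(n_pairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        if exclude_adjacent and mol[i] == mol[j] and abs(i - j) == 1:
            continue
        ti = types[i]
        tj = types[j]
        dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
        dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
        dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        u, g = _pair_eg(
            r2, eps_t[ti, tj], sig_t[ti, tj], rc_t[ti, tj],
            mode_t[ti, tj], ush_t[ti, tj], fsh_t[ti, tj],
        )
        pe += u
        fx = g * dx
        fy = g * dy
        fz = g * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        vxx += dx * fx
        vyy += dy * fy
        vzz += dz * fz
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
        dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
        dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * bond_k * (r - bond_r0) * (r - bond_r0)
        g = -bond_k * (r - bond_r0) / r
        fx = g * dx
        fy = g * dy
        fz = g * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        vxx += dx * fx
        vyy += dy * fy
        vzz += dz * fz
    return pe, vxx, vyy, vzz


@njit(cache=True, error_model="numpy", fastmath=True)
def md_chunk(
    pos, vel, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    bonds, bond_k, bond_r0, mol, exclude_adjacent,
    dt, gamma, temp, noise,
    n_steps, step0, limit_until, max_disp,
    pairs, pos_ref, forces, max_cut, skin,
    psample_every, psteps, pxx, pyy, pzz, pcount0,
):
    """Advance ``n_steps`` of BAOAB Langevin dynamics.

    ``noise`` is an (n_steps, N, 3) array of standard normals generated by
    the caller (pass a (1, 1, 1) dummy to disable the stochastic term). The
    neighbor pair list (cutoff ``max_cut + skin``) is rebuilt whenever any
    particle has moved more than skin/2 since the last build. During the
    first ``limit_until`` global steps each half-kick displacement component
    is clipped to ``max_disp`` (relaxation of random insertions).

    Pressure-tensor samples (kinetic + virial, divided by V) are appended to
    psteps/pxx/pyy/pzz every ``psample_every`` global steps.

    Returns (status, pe, pcount): status 0 ok, -1 pair-list overflow, step of
    first non-finite energy otherwise.
    """
    n = pos.shape[0]
    vol = box[0] * box[1] * box[2]
    c1 = np.exp(-gamma * dt)
    noise_on = noise.shape[0] == n_steps
    if noise_on and gamma > 0.0:
        c2 = np.sqrt(temp * (1.0 - c1 * c1))
    else:
        c2 = 0.0
    half = skin * 0.5

    n_pairs = build_pairs(pos, box, max_cut + skin, pairs)
    if n_pairs < 0:
        return -1, 0.0, pcount0
    for i in range(n):
        for a in range(3):
            pos_ref[i, a] = pos[i, a]
    pe, vxx, vyy, vzz = compute_forces(
        pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
        bonds, bond_k, bond_r0, mol, exclude_adjacent, pairs, n_pairs, forces,
    )
    pcount = pcount0
    for s in range(n_steps):
        gstep = step0 + s
        limit = gstep < limit_until
        # B half kick
        for i in range(n):
            for a in range(3):
                vel[i, a] += 0.5 * dt * forces[i, a]
        # A half drift
        for i in range(n):
            for a in range(3):
                d = 0.5 * dt * vel[i, a]
                if limit:
                    if d > max_disp:
                        d = max_disp
                    elif d < -max_disp:
                        d = -max_disp
                p = pos[i, a] + d
                pos[i, a] = p - box[a] * np.floor(p / box[a])
        # O
        if gamma > 0.0:
            if noise_on:
                for i in range(n):
                    for a in range(3):
                        vel[i, a] = c1 * vel[i, a] + c2 * noise[s, i, a]
            else:
                for i in range(n):
                    for a in range(3):
                        vel[i, a] = c1 * vel[i, a]
        # A half drift
        maxd2 = 0.0
        for i in range(n):
            for a in range(3):
                d = 0.5 * dt * vel[i, a]
                if limit:
                    if d > max_disp:
                        d = max_disp
                    elif d < -max_disp:
                        d = -max_disp
                p = pos[i, a] + d
                pos[i, a] = p - box[a] * np.floor(p / box[a])
            dx = _min_image(pos[i, 0] - pos_ref[i, 0], box[0])
            dy = _min_image(pos[i, 1] - pos_ref[i, 1], box[1])
            dz = _min_image(pos[i, 2] - pos_ref[i, 2], box[2])
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half * half:
            n_pairs = build_pairs(pos, box, max_cut + skin, pairs)
            if n_pairs < 0:
                return -1, 0.0, pcount
            for i in range(n):
                for a in range(3):
                    pos_ref[i, a] = pos[i, a]
        pe, vxx, vyy, vzz = compute_forces(
            pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
            bonds, bond_k, bond_r0, mol, exclude_adjacent, pairs, n_pairs, forces,
        )
        if not np.isfinite(pe):
            return gstep + 1, pe, pcount
        # B half kick
        for i in range(n):
            for a in range(3):
                vel[i, a] += 0.5 * dt * forces[i, a]
        if psample_every > 0 and (gstep + 1) % psample_every == 0:
            kxx = 0.0
            kyy = 0.0
            kzz = 0.0
            for i in range(n):
                kxx += vel[i, 0] * vel[i, 0]
                kyy += vel[i, 1] * vel[i, 1]
                kzz += vel[i, 2] * vel[i, 2]
            psteps[pcount] = gstep + 1
            pxx[pcount] = (kxx + vxx) / vol
            pyy[pcount] = (kyy + vyy) / vol
            pzz[pcount] = (kzz + vzz) / vol
            pcount += 1
    return 0, pe, pcount


@njit(cache=True, error_model="numpy", fastmath=True)
def total_energy(
    pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    bonds, bond_k, bond_r0, mol, exclude_adjacent,
):
    """Full O(N^2) potential energy (reference for bookkeeping checks)."""
    n = pos.shape[0]
    pe = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if exclude_adjacent and mol[i] == mol[j] and abs(i - j) == 1:
                continue
            dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
            dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
            dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            ti = types[i]
            tj = types[j]
            u, _ = _pair_eg(
                r2, eps_t[ti, tj], sig_t[ti, tj], rc_t[ti, tj],
                mode_t[ti, tj], ush_t[ti, tj], fsh_t[ti, tj],
            )
            pe += u
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
        dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
        dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * bond_k * (r - bond_r0) * (r - bond_r0)
    return pe


# ---------------------------------------------------------------------------
# Monte Carlo


@njit(cache=True, inline="always", error_model="numpy")
def _cell_of(x, y, z, box, ncx, ncy, ncz):
    cx = int(x / box[0] * ncx) % ncx
    cy = int(y / box[1] * ncy) % ncy
    cz = int(z / box[2] * ncz) % ncz
    return cx, cy, cz


@njit(cache=True, error_model="numpy")
def _bin_cells(pos, box, ncx, ncy, ncz, head, nxt):
    n = pos.shape[0]
    for c in range(head.shape[0]):
        head[c] = -1
    for i in range(n):
        cx, cy, cz = _cell_of(pos[i, 0], pos[i, 1], pos[i, 2], box, ncx, ncy, ncz)
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i


@njit(cache=True, inline="always", error_model="numpy")
def _cell_move(i, c_old, c_new, head, nxt):
    """Move particle i between linked-list cells (no-op if unchanged)."""
    if c_old == c_new:
        return
    j = head[c_old]
    if j == i:
        head[c_old] = nxt[i]
    else:
        while nxt[j] != i:
            j = nxt[j]
        nxt[j] = nxt[i]
    nxt[i] = head[c_new]
    head[c_new] = i


@njit(cache=True, inline="always", error_model="numpy", fastmath=True)
def _patchy_pair_e(dx, dy, dz, patches_i, patches_j, sigma, lam, eps, cos_ts):
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < sigma * sigma:
        return OVERLAP
    rng = sigma + lam
    if r2 >= rng * rng:
        return 0.0
    r = np.sqrt(r2)
    rx = dx / r
    ry = dy / r
    rz = dz / r
    a1 = 0
    a2 = 0
    for p in range(patches_i.shape[0]):
        if rx * patches_i[p, 0] + ry * patches_i[p, 1] + rz * patches_i[p, 2] > cos_ts:
            a1 += 1
        if -(rx * patches_j[p, 0] + ry * patches_j[p, 1] + rz * patches_j[p, 2]) > cos_ts:
            a2 += 1
    return -eps * a1 * a2


@njit(cache=True, error_model="numpy", fastmath=True)
def patchy_local_energy(
    i, x, y, z, patches_i, pos, patches, box,
    sigma, lam, eps, cos_ts, head, nxt, ncx, ncy, ncz,
):
    """Interaction energy of particle i placed at (x, y, z) with patch set
    ``patches_i``, against all other particles, via the cell grid."""
    e = 0.0
    cx0, cy0, cz0 = _cell_of(x, y, z, box, ncx, ncy, ncz)
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                c = (((cx0 + ox) % ncx) * ncy + (cy0 + oy) % ncy) * ncz + (cz0 + oz) % ncz
                j = head[c]
                while j != -1:
                    if j != i:
                        dx = _min_image(pos[j, 0] - x, box[0])
                        dy = _min_image(pos[j, 1] - y, box[1])
                        dz = _min_image(pos[j, 2] - z, box[2])
                        e += _patchy_pair_e(
                            dx, dy, dz, patches_i, patches[j],
                            sigma, lam, eps, cos_ts,
                        )
                        if e >= 0.5 * OVERLAP:
                            return OVERLAP
                    j = nxt[j]
    return e


@njit(cache=True, error_model="numpy", fastmath=True)
def patchy_local_energy_all(
    i, x, y, z, patches_i, pos, patches, box, sigma, lam, eps, cos_ts
):
    """All-pairs variant for boxes too small for a 3x3x3 cell grid."""
    e = 0.0
    for j in range(pos.shape[0]):
        if j == i:
            continue
        dx = _min_image(pos[j, 0] - x, box[0])
        dy = _min_image(pos[j, 1] - y, box[1])
        dz = _min_image(pos[j, 2] - z, box[2])
        e += _patchy_pair_e(dx, dy, dz, patches_i, patches[j], sigma, lam, eps, cos_ts)
        if e >= 0.5 * OVERLAP:
            return OVERLAP
    return e


@njit(cache=True, error_model="numpy", fastmath=True)
def patchy_total_energy(pos, patches, box, sigma, lam, eps, cos_ts):
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
            dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
            dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
            e += _patchy_pair_e(dx, dy, dz, patches[i], patches[j], sigma, lam, eps, cos_ts)
            if e >= 0.5 * OVERLAP:
                return OVERLAP
    return e


@njit(cache=True, inline="always", error_model="numpy")
def _rodrigues(axis_x, axis_y, axis_z, ang, vx, vy, vz):
    """Rotate a 3-vector about a unit axis by ang (Rodrigues formula)."""
    c = np.cos(ang)
    s = np.sin(ang)
    dot = axis_x * vx + axis_y * vy + axis_z * vz
    cx = axis_y * vz - axis_z * vy
    cy = axis_z * vx - axis_x * vz
    cz = axis_x * vy - axis_y * vx
    ox = vx * c + cx * s + axis_x * dot * (1.0 - c)
    oy = vy * c + cy * s + axis_y * dot * (1.0 - c)
    oz = vz * c + cz * s + axis_z * dot * (1.0 - c)
    return ox, oy, oz


@njit(cache=True, inline="always", error_model="numpy")
def _propose_rotation_into(axes, rot_half, new_axes):
    """Symmetric small-rotation proposal, written into ``new_axes``.

    Draws a new body z axis uniformly in the spherical cap of half-angle
    ``rot_half`` around the current z axis, rotates about the line of nodes
    (old z cross new z) to bring old z onto new z, then spins about the new z
    axis by an angle uniform in (-rot_half, rot_half). Columns are body axes
    in the lab frame.
    """
    zx = axes[0, 2]
    zy = axes[1, 2]
    zz = axes[2, 2]
    # uniform direction in the cap, in the frame of the current z axis
    cosang = 1.0 - np.random.random() * (1.0 - np.cos(rot_half))
    sinang = np.sqrt(max(0.0, 1.0 - cosang * cosang))
    phi = 2.0 * np.pi * np.random.random()
    # orthonormal frame (u, v, z)
    if abs(zx) < 0.9:
        ux = 0.0
        uy = -zz
        uz = zy
    else:
        ux = -zz
        uy = 0.0
        uz = zx
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = zy * uz - zz * uy
    vy = zz * ux - zx * uz
    vz = zx * uy - zy * ux
    nzx = sinang * (np.cos(phi) * ux + np.sin(phi) * vx) + cosang * zx
    nzy = sinang * (np.cos(phi) * uy + np.sin(phi) * vy) + cosang * zy
    nzz = sinang * (np.cos(phi) * uz + np.sin(phi) * vz) + cosang * zz
    # line of nodes = old z cross new z
    ax = zy * nzz - zz * nzy
    ay = zz * nzx - zx * nzz
    az = zx * nzy - zy * nzx
    an = np.sqrt(ax * ax + ay * ay + az * az)
    if an < 1e-14:
        for r in range(3):
            for c in range(3):
                new_axes[r, c] = axes[r, c]
    else:
        ax /= an
        ay /= an
        az /= an
        tilt = np.arccos(min(1.0, max(-1.0, cosang)))
        for c in range(3):
            ox, oy, oz = _rodrigues(
                ax, ay, az, tilt, axes[0, c], axes[1, c], axes[2, c]
            )
            new_axes[0, c] = ox
            new_axes[1, c] = oy
            new_axes[2, c] = oz
    # spin about the new z axis
    psi = (np.random.random() * 2.0 - 1.0) * rot_half
    sx = new_axes[0, 2]
    sy = new_axes[1, 2]
    sz = new_axes[2, 2]
    for c in range(2):  # z column is invariant under spin about z
        ox, oy, oz = _rodrigues(
            sx, sy, sz, psi, new_axes[0, c], new_axes[1, c], new_axes[2, c]
        )
        new_axes[0, c] = ox
        new_axes[1, c] = oy
        new_axes[2, c] = oz


@njit(cache=True, error_model="numpy")
def propose_rotation(axes, rot_half):
    """Allocating convenience wrapper around :func:`_propose_rotation_into`."""
    out = np.empty((3, 3))
    _propose_rotation_into(axes, rot_half, out)
    return out


@njit(cache=True, error_model="numpy", fastmath=True)
def mc_sweeps_patchy(
    pos, axes, patches, patch_body, box,
    sigma, lam, eps, cos_ts, temp,
    disp_half, rot_half, n_sweeps,
    head, nxt, ncx, ncy, ncz, use_cells,
    energy0,
):
    """Run ``n_sweeps`` Metropolis sweeps for Kern-Frenkel patchy particles.

    One sweep = one attempted move per particle; each attempt is a
    displacement or a rotation with equal probability. Hard-core overlaps are
    always rejected. Returns (energy, n_disp, acc_disp, n_rot, acc_rot).
    """
    n = pos.shape[0]
    beta = 1.0 / temp
    energy = energy0
    n_disp = 0
    acc_disp = 0
    n_rot = 0
    acc_rot = 0
    npatch = patch_body.shape[0]
    new_axes = np.empty((3, 3))
    new_patches = np.empty((npatch, 3))
    if use_cells:
        _bin_cells(pos, box, ncx, ncy, ncz, head, nxt)
    for _ in range(n_sweeps):
        for i in range(n):
            if np.random.random() < 0.5:
                # displacement
                n_disp += 1
                x = pos[i, 0] + (np.random.random() - 0.5) * 2.0 * disp_half
                y = pos[i, 1] + (np.random.random() - 0.5) * 2.0 * disp_half
                z = pos[i, 2] + (np.random.random() - 0.5) * 2.0 * disp_half
                x -= box[0] * np.floor(x / box[0])
                y -= box[1] * np.floor(y / box[1])
                z -= box[2] * np.floor(z / box[2])
                if use_cells:
                    e_old = patchy_local_energy(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], patches[i], pos,
                        patches, box, sigma, lam, eps, cos_ts,
                        head, nxt, ncx, ncy, ncz,
                    )
                    e_new = patchy_local_energy(
                        i, x, y, z, patches[i], pos, patches, box,
                        sigma, lam, eps, cos_ts, head, nxt, ncx, ncy, ncz,
                    )
                else:
                    e_old = patchy_local_energy_all(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], patches[i], pos,
                        patches, box, sigma, lam, eps, cos_ts,
                    )
                    e_new = patchy_local_energy_all(
                        i, x, y, z, patches[i], pos, patches, box,
                        sigma, lam, eps, cos_ts,
                    )
                if e_new < 0.5 * OVERLAP:
                    de = e_new - e_old
                    if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                        if use_cells:
                            ocx, ocy, ocz = _cell_of(
                                pos[i, 0], pos[i, 1], pos[i, 2], box, ncx, ncy, ncz
                            )
                            ncx_, ncy_, ncz_ = _cell_of(x, y, z, box, ncx, ncy, ncz)
                            _cell_move(
                                i,
                                (ocx * ncy + ocy) * ncz + ocz,
                                (ncx_ * ncy + ncy_) * ncz + ncz_,
                                head,
                                nxt,
                            )
                        pos[i, 0] = x
                        pos[i, 1] = y
                        pos[i, 2] = z
                        energy += de
                        acc_disp += 1
            else:
                # rotation
                n_rot += 1
                _propose_rotation_into(axes[i], rot_half, new_axes)
                for p in range(npatch):
                    for r in range(3):
                        new_patches[p, r] = (
                            new_axes[r, 0] * patch_body[p, 0]
                            + new_axes[r, 1] * patch_body[p, 1]
                            + new_axes[r, 2] * patch_body[p, 2]
                        )
                if use_cells:
                    e_old = patchy_local_energy(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], patches[i], pos,
                        patches, box, sigma, lam, eps, cos_ts,
                        head, nxt, ncx, ncy, ncz,
                    )
                    e_new = patchy_local_energy(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], new_patches, pos,
                        patches, box, sigma, lam, eps, cos_ts,
                        head, nxt, ncx, ncy, ncz,
                    )
                else:
                    e_old = patchy_local_energy_all(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], patches[i], pos,
                        patches, box, sigma, lam, eps, cos_ts,
                    )
                    e_new = patchy_local_energy_all(
                        i, pos[i, 0], pos[i, 1], pos[i, 2], new_patches, pos,
                        patches, box, sigma, lam, eps, cos_ts,
                    )
                de = e_new - e_old
                if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                    for r in range(3):
                        for c in range(3):
                            axes[i, r, c] = new_axes[r, c]
                    for p in range(npatch):
                        for r in range(3):
                            patches[i, p, r] = new_patches[p, r]
                    energy += de
                    acc_rot += 1
    return energy, n_disp, acc_disp, n_rot, acc_rot


@njit(cache=True, error_model="numpy", fastmath=True)
def lj_local_energy(
    i, x, y, z, pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    head, nxt, ncx, ncy, ncz, use_cells,
):
    e = 0.0
    ti = types[i]
    if use_cells:
        cx0, cy0, cz0 = _cell_of(x, y, z, box, ncx, ncy, ncz)
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    c = (((cx0 + ox) % ncx) * ncy + (cy0 + oy) % ncy) * ncz + (
                        cz0 + oz
                    ) % ncz
                    j = head[c]
                    while j != -1:
                        if j != i:
                            tj = types[j]
                            dx = _min_image(pos[j, 0] - x, box[0])
                            dy = _min_image(pos[j, 1] - y, box[1])
                            dz = _min_image(pos[j, 2] - z, box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            u, _ = _pair_eg(
                                r2, eps_t[ti, tj], sig_t[ti, tj], rc_t[ti, tj],
                                mode_t[ti, tj], ush_t[ti, tj], fsh_t[ti, tj],
                            )
                            e += u
                        j = nxt[j]
    else:
        for j in range(pos.shape[0]):
            if j == i:
                continue
            tj = types[j]
            dx = _min_image(pos[j, 0] - x, box[0])
            dy = _min_image(pos[j, 1] - y, box[1])
            dz = _min_image(pos[j, 2] - z, box[2])
            r2 = dx * dx + dy * dy + dz * dz
            u, _ = _pair_eg(
                r2, eps_t[ti, tj], sig_t[ti, tj], rc_t[ti, tj],
                mode_t[ti, tj], ush_t[ti, tj], fsh_t[ti, tj],
            )
            e += u
    return e


@njit(cache=True, error_model="numpy", fastmath=True)
def mc_sweeps_lj(
    pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    temp, disp_half, n_sweeps,
    head, nxt, ncx, ncy, ncz, use_cells, energy0,
):
    """Displacement-only Metropolis sweeps for LJ particles.

    Returns (energy, n_attempted, n_accepted).
    """
    n = pos.shape[0]
    beta = 1.0 / temp
    energy = energy0
    n_att = 0
    n_acc = 0
    if use_cells:
        _bin_cells(pos, box, ncx, ncy, ncz, head, nxt)
    for _ in range(n_sweeps):
        for i in range(n):
            n_att += 1
            x = pos[i, 0] + (np.random.random() - 0.5) * 2.0 * disp_half
            y = pos[i, 1] + (np.random.random() - 0.5) * 2.0 * disp_half
            z = pos[i, 2] + (np.random.random() - 0.5) * 2.0 * disp_half
            x -= box[0] * np.floor(x / box[0])
            y -= box[1] * np.floor(y / box[1])
            z -= box[2] * np.floor(z / box[2])
            e_old = lj_local_energy(
                i, pos[i, 0], pos[i, 1], pos[i, 2], pos, box, types,
                eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
                head, nxt, ncx, ncy, ncz, use_cells,
            )
            e_new = lj_local_energy(
                i, x, y, z, pos, box, types,
                eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
                head, nxt, ncx, ncy, ncz, use_cells,
            )
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                if use_cells:
                    ocx, ocy, ocz = _cell_of(
                        pos[i, 0], pos[i, 1], pos[i, 2], box, ncx, ncy, ncz
                    )
                    ncx_, ncy_, ncz_ = _cell_of(x, y, z, box, ncx, ncy, ncz)
                    _cell_move(
                        i,
                        (ocx * ncy + ocy) * ncz + ocz,
                        (ncx_ * ncy + ncy_) * ncz + ncz_,
                        head,
                        nxt,
                    )
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                energy += de
                n_acc += 1
    return energy, n_att, n_acc


@njit(cache=True, error_model="numpy")
def virial_tensor(
    pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
    bonds, bond_k, bond_r0, mol, exclude_adjacent, pairs,
    max_cut,
):
    """Diagonal virial components (sum r_a f_a over pairs and bonds)."""
    n_pairs = build_pairs(pos, box, max_cut, pairs)
    forces = np.zeros((pos.shape[0], 3))
    pe, vxx, vyy, vzz = compute_forces(
        pos, box, types, eps_t, sig_t, rc_t, mode_t, ush_t, fsh_t,
        bonds, bond_k, bond_r0, mol, exclude_adjacent, pairs, n_pairs, forces,
    )
    return pe, vxx, vyy, vzz
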