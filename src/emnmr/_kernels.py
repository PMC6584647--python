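"""Numba-compiled numerical kernels.

Everything here operates on flat numpy arrays so the hot loops (torsion-space
chain building, target-function evaluation, Monte-Carlo annealing, trilinear
map interpolation) run at native speed.  The public modules wrap these in
typed containers; nothing outside the package should import this module.

Atom layout: every residue owns six consecutive slots in the coordinate
array, in canonical order N, CA, C, O, CB, SC.  SC is a side-chain centroid
pseudo-atom placed colinearly beyond CB (it carries methyl-type restraints).
"""

import numpy as np
from numba import njit

N_SLOTS = 6
ATOM_ORDER = ("N", "CA", "C", "O", "CB", "SC")

# ideal trans-peptide covalent geometry (Engh & Huber-like values, Å / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.530
B_CB_SC = 1.200
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.5
D_C_N_CA_CB = -122.6  # improper fixing Cβ chirality
OMEGA = 180.0

_DEG = np.pi / 180.0


@njit(cache=True)
def _place(a, b, c, bond, angle_deg, torsion_deg, out):
    """NeRF placement: position atom d with |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    ang = angle_deg * _DEG
    tor = torsion_deg * _DEG
    ab0 = b[0] - a[0]
    ab1 = b[1] - a[1]
    ab2 = b[2] - a[2]
    bc0 = c[0] - b[0]
    bc1 = c[1] - b[1]
    bc2 = c[2] - b[2]
    nbc = np.sqrt(bc0 * bc0 + bc1 * bc1 + bc2 * bc2)
    u0 = bc0 / nbc
    u1 = bc1 / nbc
    u2 = bc2 / nbc
    n0 = ab1 * bc2 - ab2 * bc1
    n1 = ab2 * bc0 - ab0 * bc2
    n2 = ab0 * bc1 - ab1 * bc0
    nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
    n0 /= nn
    n1 /= nn
    n2 /= nn
    m0 = n1 * u2 - n2 * u1
    m1 = n2 * u0 - n0 * u2
    m2 = n0 * u1 - n1 * u0
    d0 = -bond * np.cos(ang)
    sa = bond * np.sin(ang)
    d1 = sa * np.cos(tor)
    d2 = sa * np.sin(tor)
    out[0] = c[0] + d0 * u0 + d1 * m0 + d2 * n0
    out[1] = c[1] + d0 * u1 + d1 * m1 + d2 * n1
    out[2] = c[2] + d0 * u2 + d1 * m2 + d2 * n2


@njit(cache=True)
def build_chain(phi, psi, coords):
    """Build an ideal-geometry backbone from (φ, ψ) into coords[(nres*6), 3].

    φ[0] and the ω torsions are fixed by convention (ω = 180°); ψ of the last
    residue only orients its carbonyl oxygen.
    """
    nres = phi.shape[0]
    # residue 0 in a canonical frame
    coords[0, 0] = 0.0
    coords[0, 1] = 0.0
    coords[0, 2] = 0.0
    coords[1, 0] = B_N_CA
    coords[1, 1] = 0.0
    coords[1, 2] = 0.0
    ang = (180.0 - A_N_CA_C) * _DEG
    coords[2, 0] = B_N_CA + B_CA_C * np.cos(ang)
    coords[2, 1] = B_CA_C * np.sin(ang)
    coords[2, 2] = 0.0
    for i in range(1, nres):
        p = (i - 1) * N_SLOTS
        q = i * N_SLOTS
        _place(coords[p + 0], coords[p + 1], coords[p + 2],
               B_C_N, A_CA_C_N, psi[i - 1], coords[q + 0])
        _place(coords[p + 1], coords[p + 2], coords[q + 0],
               B_N_CA, A_C_N_CA, OMEGA, coords[q + 1])
        _place(coords[p + 2], coords[q + 0], coords[q + 1],
               B_CA_C, A_N_CA_C, phi[i], coords[q + 2])
    for i in range(nres):
        q = i * N_SLOTS
        _place(coords[q + 0], coords[q + 1], coords[q + 2],
               B_C_O, A_CA_C_O, psi[i] - 180.0, coords[q + 3])
        _place(coords[q + 2], coords[q + 0], coords[q + 1],
               B_CA_CB, A_N_CA_CB, D_C_N_CA_CB, coords[q + 4])
        # SC centroid: continue the CA->CB direction
        v0 = coords[q + 4, 0] - coords[q + 1, 0]
        v1 = coords[q + 4, 1] - coords[q + 1, 1]
        v2 = coords[q + 4, 2] - coords[q + 1, 2]
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        coords[q + 5, 0] = coords[q + 4, 0] + B_CB_SC * v0 / nv
        coords[q + 5, 1] = coords[q + 4, 1] + B_CB_SC * v1 / nv
        coords[q + 5, 2] = coords[q + 4, 2] + B_CB_SC * v2 / nv


@njit(cache=True)
def _wrap_deg(x):
    while x > 180.0:
        x -= 360.0
    while x <= -180.0:
        x += 360.0
    return x


@njit(cache=True)
def tf_eval(coords, phi, psi,
            cand_i, cand_j, grp_ptr, lower, upper,
            dihe_res, dihe_is_psi, dihe_target, dihe_tol,
            steric_atoms, steric_res, steric_rmin,
            w_upper, w_lower, w_dihedral, w_steric):
    """Flat-bottom quadratic target function.

    Distance restraints may be ambiguous: candidates of restraint r live in
    cand_i/cand_j[grp_ptr[r]:grp_ptr[r+1]] and contribute through the
    r^-6-summed effective distance.  Dihedral violations are measured in
    degrees.  The steric term is a soft-sphere repulsion over the listed
    atoms for residue pairs separated by >= 2 in sequence.
    """
    tf = 0.0
    nrest = grp_ptr.shape[0] - 1
    for r in range(nrest):
        s = grp_ptr[r]
        e = grp_ptr[r + 1]
        if e - s == 1:
            ia = cand_i[s]
            ja = cand_j[s]
            dx = coords[ia, 0] - coords[ja, 0]
            dy = coords[ia, 1] - coords[ja, 1]
            dz = coords[ia, 2] - coords[ja, 2]
            d2 = dx * dx + dy * dy + dz * dz
            # satisfied restraints (the common case) never need the sqrt
            if d2 <= upper[r] * upper[r] and d2 >= lower[r] * lower[r]:
                continue
            d = np.sqrt(d2)
        else:
            acc = 0.0
            for k in range(s, e):
                ia = cand_i[k]
                ja = cand_j[k]
                dx = coords[ia, 0] - coords[ja, 0]
                dy = coords[ia, 1] - coords[ja, 1]
                dz = coords[ia, 2] - coords[ja, 2]
                d2 = dx * dx + dy * dy + dz * dz
                acc += 1.0 / (d2 * d2 * d2)
            d = acc ** (-1.0 / 6.0)
        if d > upper[r]:
            v = d - upper[r]
            tf += w_upper * v * v
        elif d < lower[r]:
            v = lower[r] - d
            tf += w_lower * v * v
    for k in range(dihe_res.shape[0]):
        i = dihe_res[k]
        ang = psi[i] if dihe_is_psi[k] == 1 else phi[i]
        dv = abs(_wrap_deg(ang - dihe_target[k]))
        if dv > dihe_tol[k]:
            v = dv - dihe_tol[k]
            tf += w_dihedral * v * v
    if w_steric > 0.0:
        ns = steric_atoms.shape[0]
        r2min = steric_rmin * steric_rmin
        for a in range(ns):
            ia = steric_atoms[a]
            ra = steric_res[a]
            for b in range(a + 1, ns):
                if steric_res[b] - ra < 2:
                    continue
                ib = steric_atoms[b]
                dx = coords[ia, 0] - coords[ib, 0]
                dy = coords[ia, 1] - coords[ib, 1]
                dz = coords[ia, 2] - coords[ib, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < r2min:
                    v = steric_rmin - np.sqrt(d2)
                    tf += w_steric * v * v
    return tf


@njit(cache=True)
def mc_anneal(phi, psi, free_mask, n_steps, t_start, t_end, seed,
              cand_i, cand_j, grp_ptr, lower, upper,
              dihe_res, dihe_is_psi, dihe_target, dihe_tol,
              steric_atoms, steric_res, steric_rmin,
              w_upper, w_lower, w_dihedral, w_steric,
              polish_steps, local_moves=0):
    """Simulated annealing over torsions with a geometric temperature schedule.

    Mutates phi/psi in place; returns the final target-function value.
    free_mask (length 2*nres: phi block then psi block) freezes torsions.
    Torsions without a dihedral restraint (loops — the degrees of freedom
    that actually set the tertiary arrangement) are proposed three times
    more often; restrained torsions are occasionally reset straight to
    their restraint target.

    With local_moves != 0 the large proposals (full-range jumps, target
    resets) are disabled: the walk refines within the seed topology and
    cannot hop basins — essential when the run starts from a model whose
    topology must be preserved.
    """
    np.random.seed(seed)
    nres = phi.shape[0]
    coords = np.empty((nres * N_SLOTS, 3))
    build_chain(phi, psi, coords)
    tf = tf_eval(coords, phi, psi, cand_i, cand_j, grp_ptr, lower, upper,
                 dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                 steric_atoms, steric_res, steric_rmin,
                 w_upper, w_lower, w_dihedral, w_steric)
    n_tor = 2 * nres
    # per-torsion restraint targets (for biased proposals) + move weights
    tor_target = np.empty(n_tor)
    tor_has = np.zeros(n_tor, dtype=np.int8)
    for m in range(dihe_res.shape[0]):
        k = dihe_res[m] + nres if dihe_is_psi[m] == 1 else dihe_res[m]
        tor_target[k] = dihe_target[m]
        tor_has[k] = 1
    move_cdf = np.empty(n_tor)
    acc = 0.0
    for k in range(n_tor):
        w = 0.0
        if free_mask[k] != 0:
            w = 1.0 if tor_has[k] == 1 else 3.0
        acc += w
        move_cdf[k] = acc
    if acc <= 0.0:
        return tf
    for k in range(n_tor):
        move_cdf[k] /= acc

    ratio = t_end / t_start
    for step in range(n_steps):
        t = t_start * ratio ** (step / n_steps)
        r = np.random.random()
        lo_k = 0
        hi_k = n_tor - 1
        while lo_k < hi_k:
            mid = (lo_k + hi_k) // 2
            if move_cdf[mid] < r:
                lo_k = mid + 1
            else:
                hi_k = mid
        k = lo_k
        if free_mask[k] == 0:
            continue
        is_psi = k >= nres
        i = k - nres if is_psi else k
        old = psi[i] if is_psi else phi[i]
        u = np.random.random()
        if local_moves != 0:
            sigma = 1.0 + 8.0 * np.sqrt(t / t_start)
            new = _wrap_deg(old + sigma * np.random.randn())
        elif tor_has[k] == 1 and u < 0.25:
            new = _wrap_deg(tor_target[k] + 8.0 * np.random.randn())
        elif u < 0.33:
            new = np.random.uniform(-180.0, 180.0)
        else:
            sigma = 2.0 + 40.0 * np.sqrt(t / t_start)
            new = _wrap_deg(old + sigma * np.random.randn())
        if is_psi:
            psi[i] = new
        else:
            phi[i] = new
        build_chain(phi, psi, coords)
        tf_new = tf_eval(coords, phi, psi, cand_i, cand_j, grp_ptr, lower,
                         upper, dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                         steric_atoms, steric_res, steric_rmin,
                         w_upper, w_lower, w_dihedral, w_steric)
        dtf = tf_new - tf
        if dtf <= 0.0 or np.random.random() < np.exp(-dtf / t):
            tf = tf_new
        else:
            if is_psi:
                psi[i] = old
            else:
                phi[i] = old
    # greedy polish: accept only improvements with small moves
    for step in range(polish_steps):
        k = np.random.randint(0, n_tor)
        if free_mask[k] == 0:
            continue
        is_psi = k >= nres
        i = k - nres if is_psi else k
        old = psi[i] if is_psi else phi[i]
        new = _wrap_deg(old + 2.0 * np.random.randn())
        if is_psi:
            psi[i] = new
        else:
            phi[i] = new
        build_chain(phi, psi, coords)
        tf_new = tf_eval(coords, phi, psi, cand_i, cand_j, grp_ptr, lower,
                         upper, dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                         steric_atoms, steric_res, steric_rmin,
                         w_upper, w_lower, w_dihedral, w_steric)
        if tf_new <= tf:
            tf = tf_new
        else:
            if is_psi:
                psi[i] = old
            else:
                phi[i] = old
    return tf


@njit(cache=True)
def coord_descent(phi, psi, free_mask,
                  cand_i, cand_j, grp_ptr, lower, upper,
                  dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                  steric_atoms, steric_res, steric_rmin,
                  w_upper, w_lower, w_dihedral, w_steric,
                  max_sweeps):
    """Deterministic cyclic coordinate descent over torsions.

    For each torsion in turn, trial steps of decreasing size are applied
    and kept when the target function improves.  Cheap, greedy, and very
    effective as a final polish after Monte-Carlo annealing.
    """
    nres = phi.shape[0]
    coords = np.empty((nres * N_SLOTS, 3))
    build_chain(phi, psi, coords)
    tf = tf_eval(coords, phi, psi, cand_i, cand_j, grp_ptr, lower, upper,
                 dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                 steric_atoms, steric_res, steric_rmin,
                 w_upper, w_lower, w_dihedral, w_steric)
    steps = np.array([16.0, 8.0, 4.0, 2.0, 1.0, 0.5])
    n_tor = 2 * nres
    for sweep in range(max_sweeps):
        improved = False
        for k in range(n_tor):
            if free_mask[k] == 0:
                continue
            is_psi = k >= nres
            i = k - nres if is_psi else k
            for si in range(steps.shape[0]):
                for sgn in (-1.0, 1.0):
                    old = psi[i] if is_psi else phi[i]
                    new = _wrap_deg(old + sgn * steps[si])
                    if is_psi:
                        psi[i] = new
                    else:
                        phi[i] = new
                    build_chain(phi, psi, coords)
                    tf_new = tf_eval(coords, phi, psi, cand_i, cand_j,
                                     grp_ptr, lower, upper, dihe_res,
                                     dihe_is_psi, dihe_target, dihe_tol,
                                     steric_atoms, steric_res, steric_rmin,
                                     w_upper, w_lower, w_dihedral, w_steric)
                    if tf_new < tf - 1e-12:
                        tf = tf_new
                        improved = True
                    else:
                        if is_psi:
                            psi[i] = old
                        else:
                            phi[i] = old
        if not improved:
            break
    return tf


@njit(cache=True)
def _map_energy(coords, bb_idx, rot, trans, ops_r, ops_t, grid, origin, voxel):
    """Mean negative normalised density over all symmetry images' backbone."""
    nb = bb_idx.shape[0]
    nops = ops_r.shape[0]
    nx, ny, nz = grid.shape
    acc = 0.0
    for a in range(nb):
        q = bb_idx[a]
        x0 = rot[0, 0] * coords[q, 0] + rot[0, 1] * coords[q, 1] + rot[0, 2] * coords[q, 2] + trans[0]
        x1 = rot[1, 0] * coords[q, 0] + rot[1, 1] * coords[q, 1] + rot[1, 2] * coords[q, 2] + trans[1]
        x2 = rot[2, 0] * coords[q, 0] + rot[2, 1] * coords[q, 1] + rot[2, 2] * coords[q, 2] + trans[2]
        for m in range(nops):
            y0 = ops_r[m, 0, 0] * x0 + ops_r[m, 0, 1] * x1 + ops_r[m, 0, 2] * x2 + ops_t[m, 0]
            y1 = ops_r[m, 1, 0] * x0 + ops_r[m, 1, 1] * x1 + ops_r[m, 1, 2] * x2 + ops_t[m, 1]
            y2 = ops_r[m, 2, 0] * x0 + ops_r[m, 2, 1] * x1 + ops_r[m, 2, 2] * x2 + ops_t[m, 2]
            fx = (y0 - origin[0]) / voxel
            fy = (y1 - origin[1]) / voxel
            fz = (y2 - origin[2]) / voxel
            ix = int(np.floor(fx))
            iy = int(np.floor(fy))
            iz = int(np.floor(fz))
            if ix < 0 or iy < 0 or iz < 0 or ix >= nx - 1 or iy >= ny - 1 or iz >= nz - 1:
                continue
            tx = fx - ix
            ty = fy - iy
            tz = fz - iz
            c00 = grid[ix, iy, iz] * (1 - tx) + grid[ix + 1, iy, iz] * tx
            c10 = grid[ix, iy + 1, iz] * (1 - tx) + grid[ix + 1, iy + 1, iz] * tx
            c01 = grid[ix, iy, iz + 1] * (1 - tx) + grid[ix + 1, iy, iz + 1] * tx
            c11 = grid[ix, iy + 1, iz + 1] * (1 - tx) + grid[ix + 1, iy + 1, iz + 1] * tx
            c0 = c00 * (1 - ty) + c10 * ty
            c1 = c01 * (1 - ty) + c11 * ty
            acc += c0 * (1 - tz) + c1 * tz
    return -acc / (nb * nops)


@njit(cache=True)
def map_coord_descent(phi, psi, free_mask, rot, trans, ops_r, ops_t,
                      grid, origin, voxel, bb_idx, w_map,
                      cand_i, cand_j, grp_ptr, lower, upper,
                      dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                      steric_atoms, steric_res, steric_rmin,
                      w_upper, w_lower, w_dihedral, w_steric,
                      max_sweeps):
    """Cyclic coordinate descent on E = TF + w_map * (negative map density).

    Strict symmetry: the protomer (after its rigid transform rot/trans) is
    replicated by every operator and all images contribute to the map term.
    """
    nres = phi.shape[0]
    coords = np.empty((nres * N_SLOTS, 3))

    def _energy():
        build_chain(phi, psi, coords)
        tf = tf_eval(coords, phi, psi, cand_i, cand_j, grp_ptr, lower, upper,
                     dihe_res, dihe_is_psi, dihe_target, dihe_tol,
                     steric_atoms, steric_res, steric_rmin,
                     w_upper, w_lower, w_dihedral, w_steric)
        me = _map_energy(coords, bb_idx, rot, trans, ops_r, ops_t,
                         grid, origin, voxel)
        return tf + w_map * me

    e = _energy()
    steps = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
    n_tor = 2 * nres
    for sweep in range(max_sweeps):
        improved = False
        for k in range(n_tor):
            if free_mask[k] == 0:
                continue
            is_psi = k >= nres
            i = k - nres if is_psi else k
            for si in range(steps.shape[0]):
                for sgn in (-1.0, 1.0):
                    old = psi[i] if is_psi else phi[i]
                    new = _wrap_deg(old + sgn * steps[si])
                    if is_psi:
                        psi[i] = new
                    else:
                        phi[i] = new
                    e_new = _energy()
                    if e_new < e - 1e-12:
                        e = e_new
                        improved = True
                    else:
                        if is_psi:
                            psi[i] = old
                        else:
                            phi[i] = old
        if not improved:
            break
    return e


@njit(cache=True)
def trilinear(grid, origin, voxel, pts, out):
    """Trilinear interpolation of grid values at Cartesian points (0 outside)."""
    nx, ny, nz = grid.shape
    for p in range(pts.shape[0]):
        fx = (pts[p, 0] - origin[0]) / voxel
        fy = (pts[p, 1] - origin[1]) / voxel
        fz = (pts[p, 2] - origin[2]) / voxel
        ix = int(np.floor(fx))
        iy = int(np.floor(fy))
        iz = int(np.floor(fz))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx - 1 or iy >= ny - 1 or iz >= nz - 1:
            out[p] = 0.0
            continue
        tx = fx - ix
        ty = fy - iy
        tz = fz - iz
        c000 = grid[ix, iy, iz]
        c100 = grid[ix + 1, iy, iz]
        c010 = grid[ix, iy + 1, iz]
        c110 = grid[ix + 1, iy + 1, iz]
        c001 = grid[ix, iy, iz + 1]
        c101 = grid[ix + 1, iy, iz + 1]
        c011 = grid[ix, iy + 1, iz + 1]
        c111 = grid[ix + 1, iy + 1, iz + 1]
        c00 = c000 * (1 - tx) + c100 * tx
        c10 = c010 * (1 - tx) + c110 * tx
        c01 = c001 * (1 - tx) + c101 * tx
        c11 = c011 * (1 - tx) + c111 * tx
        c0 = c00 * (1 - ty) + c10 * ty
        c1 = c01 * (1 - ty) + c11 * ty
        out[p] = c0 * (1 - tz) + c1 * tz


@njit(cache=True)
def trilinear_gradient(grid, origin, voxel, pts, grad):
    """Central-difference gradient of the interpolated density at points."""
    h = 0.5 * voxel
    n = pts.shape[0]
    tmp_p = np.empty(1)
    tmp_m = np.empty(1)
    shifted = np.empty((1, 3))
    for p in range(n):
        for ax in range(3):
            shifted[0, 0] = pts[p, 0]
            shifted[0, 1] = pts[p, 1]
            shifted[0, 2] = pts[p, 2]
            shifted[0, ax] += h
            trilinear(grid, origin, voxel, shifted, tmp_p)
            shifted[0, ax] -= 2 * h
            trilinear(grid, origin, voxel, shifted, tmp_m)
            grad[p, ax] = (tmp_p[0] - tmp_m[0]) / (2 * h)


@njit(cache=True)
def masked_ncc_scan(grid, origin, voxel, cand_ijk, dir_pts, tvals,
                    best_score, best_dir):
    """Masked normalized cross-correlation of a point-sampled template.

    dir_pts[d, p, :] are the template sample offsets pre-rotated for
    orientation d; tvals are the template values.  For every candidate
    voxel the best Pearson correlation over orientations and the winning
    orientation index are written to best_score / best_dir.
    """
    n_dir = dir_pts.shape[0]
    n_pts = dir_pts.shape[1]
    tmean = 0.0
    for p in range(n_pts):
        tmean += tvals[p]
    tmean /= n_pts
    tstd = 0.0
    for p in range(n_pts):
        tstd += (tvals[p] - tmean) ** 2
    tstd = np.sqrt(tstd / n_pts)
    pts = np.empty((n_pts, 3))
    vals = np.empty(n_pts)
    for c in range(cand_ijk.shape[0]):
        cx = origin[0] + voxel * cand_ijk[c, 0]
        cy = origin[1] + voxel * cand_ijk[c, 1]
        cz = origin[2] + voxel * cand_ijk[c, 2]
        sbest = -2.0
        dbest = 0
        for d in range(n_dir):
            for p in range(n_pts):
                pts[p, 0] = cx + dir_pts[d, p, 0]
                pts[p, 1] = cy + dir_pts[d, p, 1]
                pts[p, 2] = cz + dir_pts[d, p, 2]
            trilinear(grid, origin, voxel, pts, vals)
            vm = 0.0
            for p in range(n_pts):
                vm += vals[p]
            vm /= n_pts
            vs = 0.0
            cov = 0.0
            for p in range(n_pts):
                dv = vals[p] - vm
                vs += dv * dv
                cov += dv * (tvals[p] - tmean)
            vs = np.sqrt(vs / n_pts)
            if vs < 1e-12 or tstd < 1e-12:
                continue
            r = (cov / n_pts) / (vs * tstd)
            if r > sbest:
                sbest = r
                dbest = d
        best_score[c] = sbest
        best_dir[c] = dbest


@njit(cache=True)
def accumulate_gaussians(grid, origin, voxel, centers, sigma, cutoff):
    """Add a unit-amplitude 3D Gaussian of width sigma at every center."""
    nx, ny, nz = grid.shape
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    r = cutoff
    for c in range(centers.shape[0]):
        cx = centers[c, 0]
        cy = centers[c, 1]
        cz = centers[c, 2]
        i0 = max(0, int(np.floor((cx - r - origin[0]) / voxel)))
        i1 = min(nx - 1, int(np.ceil((cx + r - origin[0]) / voxel)))
        j0 = max(0, int(np.floor((cy - r - origin[1]) / voxel)))
        j1 = min(ny - 1, int(np.ceil((cy + r - origin[1]) / voxel)))
        k0 = max(0, int(np.floor((cz - r - origin[2]) / voxel)))
        k1 = min(nz - 1, int(np.ceil((cz + r - origin[2]) / voxel)))
        for i in range(i0, i1 + 1):
            dx = origin[0] + i * voxel - cx
            for j in range(j0, j1 + 1):
                dy = origin[1] + j * voxel - cy
                for k in range(k0, k1 + 1):
                    dz = origin[2] + k * voxel - cz
                    d2 = dx * dx + dy * dy + dz * dz
                    grid[i, j, k] += np.exp(-d2 * inv2s2)
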