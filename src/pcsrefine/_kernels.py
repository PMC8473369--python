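"""Numba-compiled Monte Carlo kernels for the annealing engine.

The state is a single ``(n_atoms + n_tags, 3)`` position array; metal
pseudo-atoms occupy the trailing rows.  All restraint terms are flattened to
index/limit arrays by :func:`pcsrefine.anneal.compile_system`.  Everything
here is deterministic in the seed passed to :func:`run_anneal` (numba's
per-thread RNG, single thread).
"""

from __future__ import annotations

import numpy as np
from numba import njit

PCS_PREFACTOR = 1.0e4 / (4.0 * np.pi)

# move-type selection thresholds (junction, module, torsion, metal)
_P_JUNCTION = 0.30
_P_MODULE = 0.25
_P_TORSION = 0.30


@njit(cache=True)
def _dihedral(p0, p1, p2, p3):
    b0x = p1[0] - p0[0]
    b0y = p1[1] - p0[1]
    b0z = p1[2] - p0[2]
    b1x = p2[0] - p1[0]
    b1y = p2[1] - p1[1]
    b1z = p2[2] - p1[2]
    b2x = p3[0] - p2[0]
    b2y = p3[1] - p2[1]
    b2z = p3[2] - p2[2]
    n = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    b1x /= n
    b1y /= n
    b1z /= n
    d0 = b0x * b1x + b0y * b1y + b0z * b1z
    vx = b0x - d0 * b1x
    vy = b0y - d0 * b1y
    vz = b0z - d0 * b1z
    d2 = b2x * b1x + b2y * b1y + b2z * b1z
    wx = b2x - d2 * b1x
    wy = b2y - d2 * b1y
    wz = b2z - d2 * b1z
    x = vx * wx + vy * wy + vz * wz
    cx = b1y * vz - b1z * vy
    cy = b1z * vx - b1x * vz
    cz = b1x * vy - b1y * vx
    y = cx * wx + cy * wy + cz * wz
    return np.arctan2(y, x)


@njit(cache=True)
def _module_tether_energy(pos, ref, s, e, cap):
    """Flat-bottom tether of rows [s, e) to `ref` in the module's own frame.

    The reference module is rigidly superposed (Kabsch) onto the current
    module first, so the term penalizes internal deformation only — module
    poses stay free, which is what lets PCSs re-orient modules.
    """
    n = e - s
    if n < 3:
        return 0.0
    cmx = 0.0
    cmy = 0.0
    cmz = 0.0
    rmx = 0.0
    rmy = 0.0
    rmz = 0.0
    for i in range(s, e):
        cmx += pos[i, 0]
        cmy += pos[i, 1]
        cmz += pos[i, 2]
        rmx += ref[i, 0]
        rmy += ref[i, 1]
        rmz += ref[i, 2]
    cmx /= n
    cmy /= n
    cmz /= n
    rmx /= n
    rmy /= n
    rmz /= n
    h = np.zeros((3, 3))
    for i in range(s, e):
        px = ref[i, 0] - rmx
        py = ref[i, 1] - rmy
        pz = ref[i, 2] - rmz
        qx = pos[i, 0] - cmx
        qy = pos[i, 1] - cmy
        qz = pos[i, 2] - cmz
        h[0, 0] += px * qx
        h[0, 1] += px * qy
        h[0, 2] += px * qz
        h[1, 0] += py * qx
        h[1, 1] += py * qy
        h[1, 2] += py * qz
        h[2, 0] += pz * qx
        h[2, 1] += pz * qy
        h[2, 2] += pz * qz
    u, sv, vt = np.linalg.svd(h)
    d = np.linalg.det(vt.T @ u.T)
    flip = np.eye(3)
    if d < 0.0:
        flip[2, 2] = -1.0
    rot = vt.T @ flip @ u.T  # maps centered ref onto centered current
    etot = 0.0
    for i in range(s, e):
        px = ref[i, 0] - rmx
        py = ref[i, 1] - rmy
        pz = ref[i, 2] - rmz
        fx = rot[0, 0] * px + rot[0, 1] * py + rot[0, 2] * pz + cmx
        fy = rot[1, 0] * px + rot[1, 1] * py + rot[1, 2] * pz + cmy
        fz = rot[2, 0] * px + rot[2, 1] * py + rot[2, 2] * pz + cmz
        dx = pos[i, 0] - fx
        dy = pos[i, 1] - fy
        dz = pos[i, 2] - fz
        dev = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = dev - cap
        if v > 0.0:
            etot += v * v
    return etot


@njit(cache=True)
def energy_terms(
    pos,
    up_i,
    up_j,
    up_lim,
    up_w,
    lo_i,
    lo_j,
    lo_lim,
    lo_w,
    aco_idx,
    aco_c,
    aco_h,
    pcs_spin,
    pcs_tag,
    pcs_exp,
    pcs_tol,
    pcs_w,
    chi,
    metal_rows,
    teth_ref,
    teth_cap,
    teth_mod_start,
    teth_mod_end,
    vdw_pairs,
    vdw_rmin,
    vdw_mult,
    pose_mult,
    weights,
):
    """Per-term energies: (upl, lol, aco, pcs, vdw, tether), already weighted."""
    e_upl = 0.0
    for k in range(up_i.shape[0]):
        i = up_i[k]
        j = up_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = d - up_lim[k]
        if v > 0.0:
            e_upl += up_w[k] * v * v
    e_lol = 0.0
    for k in range(lo_i.shape[0]):
        i = lo_i[k]
        j = lo_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = lo_lim[k] - d
        if v > 0.0:
            e_lol += lo_w[k] * v * v
    e_aco = 0.0
    for k in range(aco_idx.shape[0]):
        ang = _dihedral(
            pos[aco_idx[k, 0]],
            pos[aco_idx[k, 1]],
            pos[aco_idx[k, 2]],
            pos[aco_idx[k, 3]],
        )
        d = ang - aco_c[k]
        while d > np.pi:
            d -= 2.0 * np.pi
        while d < -np.pi:
            d += 2.0 * np.pi
        v = abs(d) - aco_h[k]
        if v > 0.0:
            e_aco += v * v
    e_pcs = 0.0
    for k in range(pcs_spin.shape[0]):
        t = pcs_tag[k]
        m = metal_rows[t]
        rx = pos[pcs_spin[k], 0] - pos[m, 0]
        ry = pos[pcs_spin[k], 1] - pos[m, 1]
        rz = pos[pcs_spin[k], 2] - pos[m, 2]
        r2 = rx * rx + ry * ry + rz * rz
        r5 = r2 * r2 * np.sqrt(r2)
        quad = (
            chi[t, 0, 0] * rx * rx
            + chi[t, 1, 1] * ry * ry
            + chi[t, 2, 2] * rz * rz
            + 2.0 * (chi[t, 0, 1] * rx * ry + chi[t, 0, 2] * rx * rz + chi[t, 1, 2] * ry * rz)
        )
        calc = PCS_PREFACTOR * quad / r5
        v = abs(calc - pcs_exp[k]) - pcs_tol[k]
        if v > 0.0:
            e_pcs += pcs_w[k] * v * v
    e_vdw = 0.0
    rmin = vdw_rmin * vdw_mult
    rmin2 = rmin * rmin
    for k in range(vdw_pairs.shape[0]):
        i = vdw_pairs[k, 0]
        j = vdw_pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < rmin2:
            v = rmin - np.sqrt(d2)
            e_vdw += v * v
    e_teth = 0.0
    if weights[5] > 0.0:
        for m in range(teth_mod_start.shape[0]):
            e_teth += _module_tether_energy(
                pos, teth_ref, teth_mod_start[m], teth_mod_end[m], teth_cap
            )
    # weak pose prior: the whole reference structure is superposed onto the
    # current state once, then per-atom flat-bottom deviations are summed.
    # This damps drift of the inter-module arrangement without penalizing
    # global rigid motion (the energy stays rigid-invariant).
    e_pose = 0.0
    if weights[6] * pose_mult > 0.0 and teth_mod_end.shape[0] > 0:
        n_prot = teth_mod_end[teth_mod_end.shape[0] - 1]
        e_pose = _module_tether_energy(pos, teth_ref, 0, n_prot, teth_cap)
    out = np.empty(6)
    out[0] = weights[0] * e_upl
    out[1] = weights[1] * e_lol
    out[2] = weights[2] * e_aco
    out[3] = weights[3] * e_pcs
    out[4] = weights[4] * e_vdw
    out[5] = weights[5] * e_teth + weights[6] * pose_mult * e_pose
    return out


@njit(cache=True)
def build_vdw_pairs(pos, rows, resn, cutoff):
    """Non-bonded heavy-atom pairs within `cutoff`, residue separation >= 2."""
    n = rows.shape[0]
    c2 = cutoff * cutoff
    count = 0
    for a in range(n):
        i = rows[a]
        for b in range(a + 1, n):
            j = rows[b]
            if abs(resn[a] - resn[b]) < 2:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    out = np.empty((count, 2), dtype=np.int64)
    k = 0
    for a in range(n):
        i = rows[a]
        for b in range(a + 1, n):
            j = rows[b]
            if abs(resn[a] - resn[b]) < 2:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                out[k, 0] = i
                out[k, 1] = j
                k += 1
    return out


@njit(cache=True)
def _rotate_range(pos, start, end, pivot, axis, angle):
    """Rotate rows [start, end) about `axis` (unit) through `pivot` by `angle`."""
    c = np.cos(angle)
    s = np.sin(angle)
    ux, uy, uz = axis[0], axis[1], axis[2]
    for i in range(start, end):
        px = pos[i, 0] - pivot[0]
        py = pos[i, 1] - pivot[1]
        pz = pos[i, 2] - pivot[2]
        dot = ux * px + uy * py + uz * pz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        pos[i, 0] = pivot[0] + px * c + cx * s + ux * dot * (1.0 - c)
        pos[i, 1] = pivot[1] + py * c + cy * s + uy * dot * (1.0 - c)
        pos[i, 2] = pivot[2] + pz * c + cz * s + uz * dot * (1.0 - c)


@njit(cache=True)
def _rotate_rows(pos, rows, pivot, axis, angle):
    c = np.cos(angle)
    s = np.sin(angle)
    ux, uy, uz = axis[0], axis[1], axis[2]
    for k in range(rows.shape[0]):
        i = rows[k]
        px = pos[i, 0] - pivot[0]
        py = pos[i, 1] - pivot[1]
        pz = pos[i, 2] - pivot[2]
        dot = ux * px + uy * py + uz * pz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        pos[i, 0] = pivot[0] + px * c + cx * s + ux * dot * (1.0 - c)
        pos[i, 1] = pivot[1] + py * c + cy * s + uy * dot * (1.0 - c)
        pos[i, 2] = pivot[2] + pz * c + cz * s + uz * dot * (1.0 - c)


@njit(cache=True)
def _rotate_chi(chi, t, axis, angle):
    """Rotate tag t's susceptibility matrix: χ ← R χ Rᵀ (axis-angle R)."""
    c = np.cos(angle)
    s = np.sin(angle)
    ux, uy, uz = axis[0], axis[1], axis[2]
    r = np.empty((3, 3))
    r[0, 0] = c + ux * ux * (1 - c)
    r[0, 1] = ux * uy * (1 - c) - uz * s
    r[0, 2] = ux * uz * (1 - c) + uy * s
    r[1, 0] = uy * ux * (1 - c) + uz * s
    r[1, 1] = c + uy * uy * (1 - c)
    r[1, 2] = uy * uz * (1 - c) - ux * s
    r[2, 0] = uz * ux * (1 - c) - uy * s
    r[2, 1] = uz * uy * (1 - c) + ux * s
    r[2, 2] = c + uz * uz * (1 - c)
    chi[t] = r @ chi[t] @ r.T


@njit(cache=True)
def _random_axis():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n = np.sqrt(x * x + y * y + z * z)
        if n > 1e-12:
            out = np.empty(3)
            out[0] = x / n
            out[1] = y / n
            out[2] = z / n
            return out


@njit(cache=True)
def run_anneal(
    pos0,
    # restraint arrays
    up_i,
    up_j,
    up_lim,
    up_w,
    lo_i,
    lo_j,
    lo_lim,
    lo_w,
    aco_idx,
    aco_c,
    aco_h,
    pcs_spin,
    pcs_tag,
    pcs_exp,
    pcs_tol,
    pcs_w,
    chi,
    metal_rows,
    metal_anchor_rows,
    teth_ref,
    teth_cap,
    vdw_rows,
    vdw_resn,
    vdw_rmin,
    weights,
    n_at,
    # move definitions
    junc_pivot,
    junc_start,
    mod_start,
    mod_end,
    tor_a,
    tor_b,
    tor_start,
    # schedule: per-phase arrays
    phase_steps,
    phase_t0,
    phase_t1,
    phase_vdw,
    phase_pose,
    amp_junc,
    amp_mod_rot,
    amp_mod_trans,
    amp_tor,
    amp_metal,
    amp_tensor,
    snapshot_interval,
    nb_interval,
    seed,
):
    """Phase-scheduled Metropolis annealing; returns the lowest-energy state.

    The mobile state is (atom+metal positions, per-tag tensor orientations);
    the tensor magnitudes in `chi0` stay fixed, their frames evolve.
    Returns (best_pos, best_chi, best_terms, traj, traj_steps, traj_energy,
    accepts_per_phase, t0_scale).
    """
    np.random.seed(seed)
    n_total = pos0.shape[0]
    n_tags = metal_rows.shape[0]
    pos = pos0.copy()
    backup = np.empty_like(pos)
    chi0 = chi
    chi = chi0.copy()
    chi_backup = np.empty_like(chi)
    best_chi = chi.copy()

    n_junc = junc_pivot.shape[0]
    n_mod = mod_start.shape[0]
    n_tor = tor_a.shape[0]

    total_steps = 0
    for p in range(phase_steps.shape[0]):
        total_steps += phase_steps[p]

    n_snap = total_steps // snapshot_interval + 1 if snapshot_interval > 0 else 1
    traj = np.empty((n_snap, n_total, 3))
    traj_steps = np.empty(n_snap, dtype=np.int64)
    traj_energy = np.empty(n_snap)

    skin = 1.2
    cutoff = vdw_rmin + skin
    pairs = build_vdw_pairs(pos, vdw_rows, vdw_resn, cutoff)

    vm0 = phase_vdw[0] if phase_steps.shape[0] > 0 else 1.0
    pm0 = phase_pose[0] if phase_steps.shape[0] > 0 else 1.0
    terms = energy_terms(
        pos, up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
        aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
        chi, metal_rows, teth_ref, teth_cap, mod_start, mod_end, pairs, vdw_rmin, vm0, pm0, weights,
    )
    energy = terms.sum()

    traj[0] = pos
    traj_steps[0] = 0
    traj_energy[0] = energy
    snap_k = 1

    best_pos = pos.copy()
    best_energy = energy

    # --- temperature auto-calibration: probe |ΔE| of phase-1 moves ----------
    n_probe = 64
    probes = np.empty(n_probe)
    for q in range(n_probe):
        de, _m = _try_move(
            pos, backup, chi, chi_backup, n_at, n_tags,
            junc_pivot, junc_start, mod_start, mod_end, tor_a, tor_b, tor_start,
            metal_rows, metal_anchor_rows,
            amp_junc[0], amp_mod_rot[0], amp_mod_trans[0], amp_tor[0], amp_metal[0],
            amp_tensor[0],
            up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
            aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
            teth_ref, teth_cap, pairs, vdw_rmin, vm0, pm0, weights, energy,
        )
        probes[q] = abs(de)
        # always revert probes
        _revert(pos, backup)
        chi[:] = chi_backup
    probes.sort()
    med = probes[n_probe // 2]
    t0_scale = med / 0.22314 if med > 1e-12 else 1e-9

    accepts = np.zeros(phase_steps.shape[0], dtype=np.int64)
    # adaptive per-move-type amplitude factors: keep acceptance in a useful band
    factors = np.ones(4)
    win_try = np.zeros(4)
    win_acc = np.zeros(4)
    window = 200
    gstep = 0
    for p in range(phase_steps.shape[0]):
        steps = phase_steps[p]
        if steps <= 0:
            continue
        vm = phase_vdw[p]
        pm = phase_pose[p]
        # re-evaluate at this phase's VdW / pose multipliers
        terms = energy_terms(
            pos, up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
            aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
            chi, metal_rows, teth_ref, teth_cap, mod_start, mod_end, pairs, vdw_rmin, vm, pm, weights,
        )
        energy = terms.sum()
        ratio = (phase_t1[p] / phase_t0[p]) ** (1.0 / steps)
        t_rel = phase_t0[p]
        for s in range(steps):
            t_abs = t0_scale * t_rel
            t_rel *= ratio
            de, mtype = _try_move(
                pos, backup, chi, chi_backup, n_at, n_tags,
                junc_pivot, junc_start, mod_start, mod_end, tor_a, tor_b, tor_start,
                metal_rows, metal_anchor_rows,
                amp_junc[p] * factors[0],
                amp_mod_rot[p] * factors[1],
                amp_mod_trans[p] * factors[1],
                amp_tor[p] * factors[2],
                amp_metal[p] * factors[3],
                amp_tensor[p] * factors[3],
                up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
                aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
                teth_ref, teth_cap, pairs, vdw_rmin, vm, pm, weights, energy,
            )
            if mtype >= 0:
                win_try[mtype] += 1.0
            if de <= 0.0 or np.random.random() < np.exp(-de / t_abs):
                energy += de
                accepts[p] += 1
                if mtype >= 0:
                    win_acc[mtype] += 1.0
                if energy < best_energy:
                    best_energy = energy
                    best_pos[:] = pos
                    best_chi[:] = chi
            else:
                _revert(pos, backup)
                chi[:] = chi_backup
            if gstep % window == window - 1:
                for m in range(4):
                    if win_try[m] >= 10.0:
                        rate = win_acc[m] / win_try[m]
                        if rate < 0.25:
                            factors[m] *= 0.8
                        elif rate > 0.45:
                            factors[m] *= 1.2
                        if factors[m] < 0.02:
                            factors[m] = 0.02
                        elif factors[m] > 4.0:
                            factors[m] = 4.0
                    win_try[m] = 0.0
                    win_acc[m] = 0.0
            gstep += 1
            if nb_interval > 0 and gstep % nb_interval == 0:
                pairs = build_vdw_pairs(pos, vdw_rows, vdw_resn, cutoff)
                terms = energy_terms(
                    pos, up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
                    aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
                    chi, metal_rows, teth_ref, teth_cap, mod_start, mod_end, pairs, vdw_rmin, vm, pm, weights,
                )
                energy = terms.sum()
            if snapshot_interval > 0 and gstep % snapshot_interval == 0 and snap_k < n_snap:
                traj[snap_k] = pos
                traj_steps[snap_k] = gstep
                traj_energy[snap_k] = energy
                snap_k += 1

    best_terms = energy_terms(
        best_pos, up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
        aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
        best_chi, metal_rows, teth_ref, teth_cap, mod_start, mod_end,
        build_vdw_pairs(best_pos, vdw_rows, vdw_resn, cutoff),
        vdw_rmin, 1.0, 1.0, weights,
    )
    return (
        best_pos,
        best_chi,
        best_terms,
        traj[:snap_k],
        traj_steps[:snap_k],
        traj_energy[:snap_k],
        accepts,
        t0_scale,
    )


@njit(cache=True)
def _revert(pos, backup):
    pos[:] = backup


@njit(cache=True)
def _try_move(
    pos, backup, chi, chi_backup, n_at, n_tags,
    junc_pivot, junc_start, mod_start, mod_end, tor_a, tor_b, tor_start,
    metal_rows, metal_anchor_rows,
    a_junc, a_mod_rot, a_mod_trans, a_tor, a_metal, a_tensor,
    up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
    aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
    teth_ref, teth_cap, pairs, vdw_rmin, vdw_mult, pose_mult, weights, energy_old,
):
    """Apply one random trial move in place; return (ΔE, move type).

    Move types: 0 junction, 1 module, 2 torsion, 3 metal/tensor, -1 none.
    Tags ride their modules: when a junction or module move displaces a
    tag's anchor, the metal translates and the tensor frame co-rotates.
    """
    backup[:] = pos
    chi_backup[:] = chi
    n_junc = junc_pivot.shape[0]
    n_mod = mod_start.shape[0]
    n_tor = tor_a.shape[0]
    mtype = -1
    u = np.random.random()
    if u < _P_JUNCTION and n_junc > 0:
        mtype = 0
        k = np.random.randint(n_junc)
        axis = _random_axis()
        angle = (2.0 * np.random.random() - 1.0) * a_junc
        pivot = pos[junc_pivot[k]].copy()
        start = junc_start[k]
        _rotate_range(pos, start, n_at, pivot, axis, angle)
        for t in range(n_tags):
            if metal_anchor_rows[t] >= start:
                _rotate_range(pos, metal_rows[t], metal_rows[t] + 1, pivot, axis, angle)
                _rotate_chi(chi, t, axis, angle)
    elif u < _P_JUNCTION + _P_MODULE and n_mod > 0:
        mtype = 1
        k = np.random.randint(n_mod)
        s, e = mod_start[k], mod_end[k]
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for i in range(s, e):
            cx += pos[i, 0]
            cy += pos[i, 1]
            cz += pos[i, 2]
        cent = np.empty(3)
        cent[0] = cx / (e - s)
        cent[1] = cy / (e - s)
        cent[2] = cz / (e - s)
        axis = _random_axis()
        angle = (2.0 * np.random.random() - 1.0) * a_mod_rot
        _rotate_range(pos, s, e, cent, axis, angle)
        tx = np.random.normal() * a_mod_trans
        ty = np.random.normal() * a_mod_trans
        tz = np.random.normal() * a_mod_trans
        for i in range(s, e):
            pos[i, 0] += tx
            pos[i, 1] += ty
            pos[i, 2] += tz
        for t in range(n_tags):
            if s <= metal_anchor_rows[t] < e:
                m = metal_rows[t]
                _rotate_range(pos, m, m + 1, cent, axis, angle)
                _rotate_chi(chi, t, axis, angle)
                pos[m, 0] += tx
                pos[m, 1] += ty
                pos[m, 2] += tz
    elif u < _P_JUNCTION + _P_MODULE + _P_TORSION and n_tor > 0:
        mtype = 2
        k = np.random.randint(n_tor)
        a = tor_a[k]
        b = tor_b[k]
        axis = pos[b] - pos[a]
        axis /= np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
        angle = (2.0 * np.random.random() - 1.0) * a_tor
        pivot = pos[b].copy()
        start = tor_start[k]
        _rotate_range(pos, start, n_at, pivot, axis, angle)
        for t in range(n_tags):
            if metal_anchor_rows[t] >= start:
                _rotate_range(pos, metal_rows[t], metal_rows[t] + 1, pivot, axis, angle)
                _rotate_chi(chi, t, axis, angle)
    elif n_tags > 0:
        mtype = 3
        t = np.random.randint(n_tags)
        m = metal_rows[t]
        if a_tensor > 0.0 and np.random.random() < 0.5:
            # free tensor-frame rotation (off when the orientation is slaved
            # to the anchor module, i.e. a_tensor == 0)
            axis = _random_axis()
            angle = (2.0 * np.random.random() - 1.0) * a_tensor
            _rotate_chi(chi, t, axis, angle)
        else:
            pos[m, 0] += np.random.normal() * a_metal
            pos[m, 1] += np.random.normal() * a_metal
            pos[m, 2] += np.random.normal() * a_metal
    else:
        return 0.0, mtype

    terms = energy_terms(
        pos, up_i, up_j, up_lim, up_w, lo_i, lo_j, lo_lim, lo_w,
        aco_idx, aco_c, aco_h, pcs_spin, pcs_tag, pcs_exp, pcs_tol, pcs_w,
        chi, metal_rows, teth_ref, teth_cap, mod_start, mod_end, pairs, vdw_rmin, vdw_mult, pose_mult, weights,
    )
    return terms.sum() - energy_old, mtype
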