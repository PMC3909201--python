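"""Numba-compiled inner loops: potential terms, forces, BAOAB Langevin.

All kernels work on plain float64/int64 arrays in reduced units (ε = 1,
k_B = 1, bead mass = 1, lengths in Å).  Forces are accumulated into a
caller-provided (n, 3) array; each term returns its energy contribution.
Degenerate geometry (r → 0, collinear angles) produces non-finite numbers
that the Python wrappers translate into errors.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bond_term(x, f, r0, kb):
    e = 0.0
    n = x.shape[0]
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[i]
        e += kb * dr * dr
        c = 2.0 * kb * dr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[i + 1, 0] -= c * dx
        f[i + 1, 1] -= c * dy
        f[i + 1, 2] -= c * dz
    return e


@njit(cache=True)
def angle_term(x, f, th0, ka):
    e = 0.0
    n = x.shape[0]
    for i in range(n - 2):
        # vertex at i+1; arms toward i and i+2
        ux = x[i, 0] - x[i + 1, 0]
        uy = x[i, 1] - x[i + 1, 1]
        uz = x[i, 2] - x[i + 1, 2]
        wx = x[i + 2, 0] - x[i + 1, 0]
        wy = x[i + 2, 1] - x[i + 1, 1]
        wz = x[i + 2, 2] - x[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        cost = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        th = np.arccos(cost)
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        dth = th - th0[i]
        e += ka * dth * dth
        dedth = 2.0 * ka * dth
        # ∂θ/∂(atom i) and ∂θ/∂(atom i+2)
        cu = 1.0 / (nu * sint)
        cw = 1.0 / (nw * sint)
        dux = (cost * ux / nu - wx / nw) * cu
        duy = (cost * uy / nu - wy / nw) * cu
        duz = (cost * uz / nu - wz / nw) * cu
        dwx = (cost * wx / nw - ux / nu) * cw
        dwy = (cost * wy / nw - uy / nu) * cw
        dwz = (cost * wz / nw - uz / nu) * cw
        f[i, 0] -= dedth * dux
        f[i, 1] -= dedth * duy
        f[i, 2] -= dedth * duz
        f[i + 2, 0] -= dedth * dwx
        f[i + 2, 1] -= dedth * dwy
        f[i + 2, 2] -= dedth * dwz
        f[i + 1, 0] += dedth * (dux + dwx)
        f[i + 1, 1] += dedth * (duy + dwy)
        f[i + 1, 2] += dedth * (duz + dwz)
    return e


@njit(cache=True)
def dihedral_term(x, f, phi0, k1, k3):
    e = 0.0
    n = x.shape[0]
    for i in range(n - 3):
        b1x = x[i + 1, 0] - x[i, 0]
        b1y = x[i + 1, 1] - x[i, 1]
        b1z = x[i + 1, 2] - x[i, 2]
        b2x = x[i + 2, 0] - x[i + 1, 0]
        b2y = x[i + 2, 1] - x[i + 1, 1]
        b2z = x[i + 2, 2] - x[i + 1, 2]
        b3x = x[i + 3, 0] - x[i + 2, 0]
        b3y = x[i + 3, 1] - x[i + 2, 1]
        b3z = x[i + 3, 2] - x[i + 2, 2]
        # n1 = b1 × b2, n2 = b2 × b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # φ = atan2((n1 × b̂2)·n2, n1·n2)
        cxx = n1y * b2z - n1z * b2y
        cxy = n1z * b2x - n1x * b2z
        cxz = n1x * b2y - n1y * b2x
        ycomp = (cxx * n2x + cxy * n2y + cxz * n2z) / nb2
        xcomp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(ycomp, xcomp)
        dphi = phi - phi0[i]
        e += k1 * (1.0 - np.cos(dphi)) + k3 * (1.0 - np.cos(3.0 * dphi))
        dedphi = k1 * np.sin(dphi) + 3.0 * k3 * np.sin(3.0 * dphi)
        sq1 = n1x * n1x + n1y * n1y + n1z * n1z
        sq2 = n2x * n2x + n2y * n2y + n2z * n2z
        if sq1 < 1e-12:
            sq1 = 1e-12
        if sq2 < 1e-12:
            sq2 = 1e-12
        ca = nb2 / sq1
        cb = -nb2 / sq2
        # ∂φ/∂x for the four beads
        d1x = ca * n1x
        d1y = ca * n1y
        d1z = ca * n1z
        d4x = cb * n2x
        d4y = cb * n2y
        d4z = cb * n2z
        t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        d2x = -(1.0 + t1) * d1x + t2 * d4x
        d2y = -(1.0 + t1) * d1y + t2 * d4y
        d2z = -(1.0 + t1) * d1z + t2 * d4z
        d3x = t1 * d1x - (1.0 + t2) * d4x
        d3y = t1 * d1y - (1.0 + t2) * d4y
        d3z = t1 * d1z - (1.0 + t2) * d4z
        f[i, 0] -= dedphi * d1x
        f[i, 1] -= dedphi * d1y
        f[i, 2] -= dedphi * d1z
        f[i + 1, 0] -= dedphi * d2x
        f[i + 1, 1] -= dedphi * d2y
        f[i + 1, 2] -= dedphi * d2z
        f[i + 2, 0] -= dedphi * d3x
        f[i + 2, 1] -= dedphi * d3y
        f[i + 2, 2] -= dedphi * d3z
        f[i + 3, 0] -= dedphi * d4x
        f[i + 3, 1] -= dedphi * d4y
        f[i + 3, 2] -= dedphi * d4z
    return e


@njit(cache=True)
def contact_term(x, f, ci, cj, cr0, cw, eps, form):
    """Native-contact wells.  form 0: 12–10 Gō well; form 1: 12–6."""
    e = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = cr0[k] / r
        s2 = s * s
        s6 = s2 * s2 * s2
        s10 = s6 * s2 * s2
        s12 = s6 * s6
        d = cw[k] * eps
        if form == 0:
            e += d * (5.0 * s12 - 6.0 * s10)
            dedr = 60.0 * d * (s10 - s12) / r
        else:
            e += d * (s12 - 2.0 * s6)
            dedr = 12.0 * d * (s6 - s12) / r
        c = -dedr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    return e


@njit(cache=True)
def repulsion_term(x, f, ri, rj, eps, sig, rcut):
    """Excluded-volume (σ/r)¹² repulsion over non-native, non-frustration
    pairs.  With rcut > 0 the term is truncated at rcut and energy- and
    force-shifted so both vanish continuously there; rcut ≤ 0 disables
    truncation (pure power law)."""
    e = 0.0
    eshift = 0.0
    fshift = 0.0
    if rcut > 0.0:
        sc = sig / rcut
        sc2 = sc * sc
        sc12 = sc2 * sc2 * sc2
        sc12 = sc12 * sc12
        eshift = sc12
        fshift = 12.0 * sc12 / rcut
    for k in range(ri.shape[0]):
        i = ri[k]
        j = rj[k]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if rcut > 0.0 and r >= rcut:
            continue
        s = sig / r
        s2 = s * s
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        if rcut > 0.0:
            e += eps * (s12 - eshift + fshift * (r - rcut))
            dedr = eps * (-12.0 * s12 / r + fshift)
        else:
            e += eps * s12
            dedr = -12.0 * eps * s12 / r
        c = -dedr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    return e


@njit(cache=True)
def frustration_term(x, f, fi, fj, epsf, cf):
    """Non-native hydrophobic attraction: 12–6 well of depth ε_f with its
    minimum at C_f (which doubles as the native-contact detection cutoff)."""
    e = 0.0
    for k in range(fi.shape[0]):
        i = fi[k]
        j = fj[k]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = cf / r
        s2 = s * s
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e += epsf * (s12 - 2.0 * s6)
        dedr = 12.0 * epsf * (s6 - s12) / r
        c = -dedr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    return e


@njit(cache=True)
def total_force(x, f, bond_r0, th0, phi0, ci, cj, cr0, cw, ri, rj, fi, fj,
                kb, ka, k1, k3, eps, sig, rcut, epsf, cf, form):
    f[:] = 0.0
    eb = bond_term(x, f, bond_r0, kb)
    ea = angle_term(x, f, th0, ka)
    ed = dihedral_term(x, f, phi0, k1, k3)
    en = contact_term(x, f, ci, cj, cr0, cw, eps, form)
    er = repulsion_term(x, f, ri, rj, eps, sig, rcut)
    ef = frustration_term(x, f, fi, fj, epsf, cf)
    return eb, ea, ed, en, er, ef


@njit(cache=True)
def run_protein_segment(x, v, bond_r0, th0, phi0, ci, cj, cr0, cw, ri, rj,
                        fi, fj, kb, ka, k1, k3, eps, sig, rcut, epsf, cf,
                        form, dt, gamma, temperature, mass, n_steps, stride,
                        seed, snap_out):
    """Propagate BAOAB Langevin dynamics for ``n_steps`` in place.

    Snapshots (coordinates) are stored into ``snap_out`` every ``stride``
    steps (at steps stride-1, 2*stride-1, ...).  Returns
    ``(n_snapshots, status)`` where status is −1 on success or the step index
    at which a bead moved more than 1 Å in a single step (instability).
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros((n, 3))
    total_force(x, f, bond_r0, th0, phi0, ci, cj, cr0, cw, ri, rj, fi, fj,
                kb, ka, k1, k3, eps, sig, rcut, epsf, cf, form)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature / mass)
    half = 0.5 * dt
    halfm = 0.5 * dt / mass
    nsnap = 0
    for step in range(n_steps):
        maxdisp2 = 0.0
        for i in range(n):
            for d in range(3):
                v[i, d] += halfm * f[i, d]
                xo = x[i, d]
                x[i, d] += half * v[i, d]
                v[i, d] = c1 * v[i, d] + c2 * np.random.standard_normal()
                x[i, d] += half * v[i, d]
                disp = x[i, d] - xo
                disp2 = disp * disp
                if disp2 > maxdisp2:
                    maxdisp2 = disp2
        # full-step displacement per coordinate > 1 Å signals a blow-up
        if maxdisp2 > 1.0 or not np.isfinite(maxdisp2):
            return nsnap, step
        total_force(x, f, bond_r0, th0, phi0, ci, cj, cr0, cw, ri, rj, fi, fj,
                    kb, ka, k1, k3, eps, sig, rcut, epsf, cf, form)
        for i in range(n):
            for d in range(3):
                v[i, d] += halfm * f[i, d]
        if (step + 1) % stride == 0:
            for i in range(n):
                for d in range(3):
                    snap_out[nsnap, i, d] = x[i, d]
            nsnap += 1
    return nsnap, -1


@njit(cache=True)
def dw_force(x, h, dl, dr, a_l, a_r):
    """Piecewise-quartic asymmetric double well, C¹ at x = 0.

    Left well:  (h+dl)·((x/a_l)²−1)² − dl   (minimum −dl at −a_l)
    Right well: (h+dr)·((x/a_r)²−1)² − dr   (minimum −dr at +a_r)
    Both branches equal h at x = 0 with zero slope.
    """
    if x < 0.0:
        u = x / a_l
        return -4.0 * (h + dl) * u * (u * u - 1.0) / a_l
    u = x / a_r
    return -4.0 * (h + dr) * u * (u * u - 1.0) / a_r


@njit(cache=True)
def run_dw_segment(state, h, dl, dr, a_l, a_r, dt, gamma, temperature,
                   n_steps, stride, seed, snap_out):
    """1-D BAOAB for the double-well toy; state = [x, v] updated in place.
    Stores x into snap_out every stride steps; returns snapshot count."""
    np.random.seed(seed)
    x = state[0]
    v = state[1]
    f = dw_force(x, h, dl, dr, a_l, a_r)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature)
    half = 0.5 * dt
    nsnap = 0
    for step in range(n_steps):
        v += half * f
        x += half * v
        v = c1 * v + c2 * np.random.standard_normal()
        x += half * v
        f = dw_force(x, h, dl, dr, a_l, a_r)
        v += half * f
        if (step + 1) % stride == 0:
            snap_out[nsnap] = x
            nsnap += 1
    state[0] = x
    state[1] = v
    return nsnap
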