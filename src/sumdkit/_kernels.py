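"""Numba-compiled inner loops for bonded and nonbonded terms.

All kernels work on precomputed pair index arrays and return energies in
kcal/mol, forces in kcal/mol/Å.  Overlapping nonbonded pairs (r < 1e-6 Å)
are reported back as a pair index (singularity) and raised by the callers;
kernels themselves never raise.

Lennard-Jones uses the rmin/epsilon 12-6 form
``E = eps * ((rmin/r)^12 - 2 (rmin/r)^6)`` with an optional CHARMM-style
switching function between ``r_on`` and ``r_cut``; Coulomb is plain
``qq/r`` (``qq`` pre-scaled by k_e and the relative dielectric), truncated
at ``r_cut`` when cutoffs are enabled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OVERLAP = 1.0e-6


@njit(cache=False)
def harmonic_terms(coords, idx_i, idx_j, ks, r0s, forces):
    """Harmonic bonds / elastic pairs, E = 0.5 * k * (r - r0)^2."""
    e = 0.0
    for p in range(idx_i.size):
        i = idx_i[p]
        j = idx_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _OVERLAP:
            r = _OVERLAP
        dr = r - r0s[p]
        e += 0.5 * ks[p] * dr * dr
        fmag = -ks[p] * dr / r  # force along (xi - xj) on atom i
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=False)
def restraint_terms(coords, idx, ks, refs, forces):
    """Harmonic positional restraints E = 0.5 k |x - x_ref|^2."""
    e = 0.0
    for p in range(idx.size):
        i = idx[p]
        for d in range(3):
            dx = coords[i, d] - refs[p, d]
            e += 0.5 * ks[p] * dx * dx
            forces[i, d] -= ks[p] * dx
    return e


@njit(cache=False, fastmath=True)
def nonbonded_terms(
    coords, idx_i, idx_j, qq, rmin, eps, use_cutoff, r_on, r_cut, kappa, forces
):
    """Coulomb + 12-6 LJ over a pair list, accumulating forces.

    Returns (elec, vdw, bad_pair): bad_pair is -1 normally, else the index
    of the first overlapping pair.
    """
    e_el = 0.0
    e_vdw = 0.0
    rc2 = r_cut * r_cut
    ron2 = r_on * r_on
    denom = (rc2 - ron2) ** 3
    for p in range(idx_i.size):
        i = idx_i[p]
        j = idx_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _OVERLAP * _OVERLAP:
            return e_el, e_vdw, p
        if use_cutoff and r2 >= rc2:
            continue
        r = np.sqrt(r2)
        # Coulomb (optionally Debye-screened; truncated at cutoff if enabled)
        if qq[p] != 0.0:
            if kappa > 0.0:
                e_c = qq[p] * np.exp(-kappa * r) / r
                de_c = -e_c * (1.0 / r + kappa)  # dE/dr
            else:
                e_c = qq[p] / r
                de_c = -qq[p] / r2  # dE/dr
        else:
            e_c = 0.0
            de_c = 0.0
        # LJ
        sr2 = (rmin[p] * rmin[p]) / r2
        sr6 = sr2 * sr2 * sr2
        e_lj = eps[p] * (sr6 * sr6 - 2.0 * sr6)
        de_lj = 12.0 * eps[p] * (sr6 - sr6 * sr6) / r
        if use_cutoff and r2 > ron2:
            # CHARMM switch on the LJ term only
            a = rc2 - r2
            b = rc2 + 2.0 * r2 - 3.0 * ron2
            s = a * a * b / denom
            ds = 4.0 * r * a * (a - b) / denom
            de_lj = de_lj * s + e_lj * ds
            e_lj = e_lj * s
        e_el += e_c
        e_vdw += e_lj
        de = de_c + de_lj
        fmag = -de / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e_el, e_vdw, -1


@njit(cache=False)
def nonbonded_pair_energies(
    coords, idx_i, idx_j, qq, rmin, eps, use_cutoff, r_on, r_cut, kappa, e_el, e_vdw
):
    """Per-pair Coulomb and LJ energies (no forces), for decompositions."""
    rc2 = r_cut * r_cut
    ron2 = r_on * r_on
    denom = (rc2 - ron2) ** 3
    for p in range(idx_i.size):
        i = idx_i[p]
        j = idx_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _OVERLAP * _OVERLAP:
            return p
        e_el[p] = 0.0
        e_vdw[p] = 0.0
        if use_cutoff and r2 >= rc2:
            continue
        r = np.sqrt(r2)
        if qq[p] != 0.0:
            if kappa > 0.0:
                e_el[p] = qq[p] * np.exp(-kappa * r) / r
            else:
                e_el[p] = qq[p] / r
        sr2 = (rmin[p] * rmin[p]) / r2
        sr6 = sr2 * sr2 * sr2
        e = eps[p] * (sr6 * sr6 - 2.0 * sr6)
        if use_cutoff and r2 > ron2:
            a = rc2 - r2
            b = rc2 + 2.0 * r2 - 3.0 * ron2
            e *= a * a * b / denom
        e_vdw[p] = e
    return -1


@njit(cache=False, fastmath=True)
def integrate_baoab(
    x,
    v,
    inv_m_akma,  # KCAL_TO_AKMA / m, per atom
    sigma,  # sqrt(kB T KCAL_TO_AKMA / m), per atom
    bi, bj, bk, br0,  # bonds + elastic pairs, concatenated
    ridx, rks, rrefs,  # positional restraints
    nbi, nbj, qq, rmin, eps,  # nonbonded pair table (qq pre-scaled)
    use_cutoff, r_on, r_cut, kappa,
    dt, c1, c2,
    n_steps, snap_every,
    noise,  # (n_steps, 3*n) pre-drawn standard normals (unused if c2 == 0)
    snaps_x, snaps_v,  # preallocated (n_snaps, n, 3)
):
    """Fused BAOAB loop; returns (status, step): status 0 ok, 1 overlap
    singularity, 2 non-finite blow-up."""
    n = x.shape[0]
    f = np.zeros((n, 3))
    harmonic_terms(x, bi, bj, bk, br0, f)
    if ridx.size:
        restraint_terms(x, ridx, rks, rrefs, f)
    e_el, e_vdw, bad = nonbonded_terms(
        x, nbi, nbj, qq, rmin, eps, use_cutoff, r_on, r_cut, kappa, f
    )
    if bad >= 0:
        return 1, 0
    snap = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m_akma[i]
                x[i, d] += 0.5 * dt * v[i, d]
        if c2 > 0.0:
            k = 0
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * sigma[i] * noise[step - 1, k]
                    k += 1
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
                f[i, d] = 0.0
        harmonic_terms(x, bi, bj, bk, br0, f)
        if ridx.size:
            restraint_terms(x, ridx, rks, rrefs, f)
        e_el, e_vdw, bad = nonbonded_terms(
            x, nbi, nbj, qq, rmin, eps, use_cutoff, r_on, r_cut, kappa, f
        )
        if bad >= 0:
            return 1, step
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d] * inv_m_akma[i]
        if step % snap_every == 0:
            ok = True
            for i in range(n):
                for d in range(3):
                    val = x[i, d]
                    if not (val == val) or val > 1.0e8 or val < -1.0e8:
                        ok = False
            if not ok:
                return 2, step
            for i in range(n):
                for d in range(3):
                    snaps_x[snap, i, d] = x[i, d]
                    snaps_v[snap, i, d] = v[i, d]
            snap += 1
    return 0, n_steps
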