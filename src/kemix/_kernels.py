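"""Numba kernels: non-bonded pair sums (cell list with O(N²) fallback),
harmonic bonds, both returning energy and the diagonal virial.

Force convention: for a pair (i, j) with d = r_i - r_j, the force on i is
fr * d where fr = -(1/r) dU/dr; the pair virial contribution to W_aa is
fr * d_a².  All boxes are orthorhombic and fully periodic (minimum image).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_1_3 = 2.0 ** (1.0 / 3.0)


@njit(cache=True, fastmath=True, inline="always")
def _pair_terms(r2, ti, tj, sigma2, lam, eps, lj_shift, qq, kappa, dh_shift,
                rc_pair2, rc_elec2):
    if r2 < 0.25:
        r2 = 0.25
    e = 0.0
    fr = 0.0
    if r2 < rc_pair2:
        s2 = sigma2[ti, tj] / r2
        s6 = s2 * s2 * s2
        ulj = 4.0 * eps * (s6 * s6 - s6)
        flj = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        l = lam[ti, tj]
        if r2 < TWO_1_3 * sigma2[ti, tj]:
            e += ulj + (1.0 - l) * eps - l * lj_shift[ti, tj]
            fr += flj
        else:
            e += l * (ulj - lj_shift[ti, tj])
            fr += l * flj
    q = qq[ti, tj]
    if q != 0.0 and r2 < rc_elec2:
        r = np.sqrt(r2)
        ed = q / r * np.exp(-kappa * r)
        e += ed - dh_shift[ti, tj]
        fr += ed * (1.0 / r2 + kappa / r)
    return e, fr


@njit(cache=True, fastmath=True, inline="always")
def _excluded(i, j, excl, n_excl):
    for k in range(n_excl[i]):
        if excl[i, k] == j:
            return True
    return False


@njit(cache=True, fastmath=True)
def _brute_force(pos, box, types, excl, n_excl, sigma2, lam, eps, lj_shift,
                 qq, kappa, dh_shift, rc_pair2, rc_elec2, rc_max2, forces):
    n = pos.shape[0]
    epot = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc_max2 or _excluded(i, j, excl, n_excl):
                continue
            e, fr = _pair_terms(r2, types[i], types[j], sigma2, lam, eps,
                                lj_shift, qq, kappa, dh_shift,
                                rc_pair2, rc_elec2)
            epot += e
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
            wxx += fr * dx * dx
            wyy += fr * dy * dy
            wzz += fr * dz * dz
    return epot, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def _cell_force(pos, box, types, excl, n_excl, sigma2, lam, eps, lj_shift,
                qq, kappa, dh_shift, rc_pair2, rc_elec2, rc_max2,
                ncx, ncy, ncz, forces):
    n = pos.shape[0]
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (cz * ncy + cy) * ncx + cx
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i

    # 13 half-space neighbour offsets + the home cell
    offsets = np.array([
        (1, 0, 0), (0, 1, 0), (1, 1, 0), (-1, 1, 0),
        (0, 0, 1), (1, 0, 1), (-1, 0, 1), (0, 1, 1), (0, -1, 1),
        (1, 1, 1), (-1, 1, 1), (1, -1, 1), (-1, -1, 1),
    ], dtype=np.int64)

    epot = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                # home cell, i < j by list order
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        dx -= box[0] * np.rint(dx / box[0])
                        dy -= box[1] * np.rint(dy / box[1])
                        dz -= box[2] * np.rint(dz / box[2])
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 <= rc_max2 and not _excluded(i, j, excl, n_excl):
                            e, fr = _pair_terms(
                                r2, types[i], types[j], sigma2, lam, eps,
                                lj_shift, qq, kappa, dh_shift,
                                rc_pair2, rc_elec2)
                            epot += e
                            forces[i, 0] += fr * dx
                            forces[i, 1] += fr * dy
                            forces[i, 2] += fr * dz
                            forces[j, 0] -= fr * dx
                            forces[j, 1] -= fr * dy
                            forces[j, 2] -= fr * dz
                            wxx += fr * dx * dx
                            wyy += fr * dy * dy
                            wzz += fr * dz * dz
                        j = nxt[j]
                    i = nxt[i]
                # neighbour cells
                for k in range(13):
                    ox = (cx + offsets[k, 0]) % ncx
                    oy = (cy + offsets[k, 1]) % ncy
                    oz = (cz + offsets[k, 2]) % ncz
                    c2 = (oz * ncy + oy) * ncx + ox
                    i = head[c]
                    while i >= 0:
                        j = head[c2]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box[0] * np.rint(dx / box[0])
                            dy -= box[1] * np.rint(dy / box[1])
                            dz -= box[2] * np.rint(dz / box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 <= rc_max2 and not _excluded(
                                    i, j, excl, n_excl):
                                e, fr = _pair_terms(
                                    r2, types[i], types[j], sigma2, lam, eps,
                                    lj_shift, qq, kappa, dh_shift,
                                    rc_pair2, rc_elec2)
                                epot += e
                                forces[i, 0] += fr * dx
                                forces[i, 1] += fr * dy
                                forces[i, 2] += fr * dz
                                forces[j, 0] -= fr * dx
                                forces[j, 1] -= fr * dy
                                forces[j, 2] -= fr * dz
                                wxx += fr * dx * dx
                                wyy += fr * dy * dy
                                wzz += fr * dz * dz
                            j = nxt[j]
                        i = nxt[i]
    return epot, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def nonbonded(pos, box, types, excl, n_excl, sigma2, lam, eps, lj_shift,
              qq, kappa, dh_shift, rc_pair2, rc_elec2, forces):
    rc_max2 = max(rc_pair2, rc_elec2)
    rc = np.sqrt(rc_max2)
    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    if ncx >= 3 and ncy >= 3 and ncz >= 3:
        return _cell_force(pos, box, types, excl, n_excl, sigma2, lam, eps,
                           lj_shift, qq, kappa, dh_shift, rc_pair2, rc_elec2,
                           rc_max2, ncx, ncy, ncz, forces)
    return _brute_force(pos, box, types, excl, n_excl, sigma2, lam, eps,
                        lj_shift, qq, kappa, dh_shift, rc_pair2, rc_elec2,
                        rc_max2, forces)


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, rlist2, excl, n_excl, pi, pj):
    """Fill the Verlet pair list (bonded exclusions applied at build time).

    Returns the pair count, or -1 if the preallocated arrays are too small.
    """
    n = pos.shape[0]
    count = 0
    cap = pi.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2 and not _excluded(i, j, excl, n_excl):
                if count >= cap:
                    return -1
                pi[count] = i
                pj[count] = j
                count += 1
    return count


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, pi, pj, npairs, types, sigma2, lam, eps, lj_shift,
                qq, kappa, dh_shift, rc_pair2, rc_elec2, forces):
    """Non-bonded forces/energy/virial over a prebuilt pair list.

    Positions must be wrapped into the primary box (|Δ| < box per axis), so
    the minimum image reduces to a single add/subtract per axis.
    """
    rc_max2 = max(rc_pair2, rc_elec2)
    bx = box[0]
    by = box[1]
    bz = box[2]
    hx = 0.5 * bx
    hy = 0.5 * by
    hz = 0.5 * bz
    epot = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > hx:
            dx -= bx
        elif dx < -hx:
            dx += bx
        if dy > hy:
            dy -= by
        elif dy < -hy:
            dy += by
        if dz > hz:
            dz -= bz
        elif dz < -hz:
            dz += bz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rc_max2:
            continue
        if r2 < 0.25:
            # guard against overlapping beads: treat them as 0.5 Å apart so
            # the force stays finite; the integrator's temperature guard
            # aborts if such contacts persist
            r2 = 0.25
        ti = types[i]
        tj = types[j]
        inv_r2 = 1.0 / r2
        e = 0.0
        fr = 0.0
        if r2 < rc_pair2:
            s2 = sigma2[ti, tj] * inv_r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            ulj = 4.0 * eps * (s12 - s6)
            flj = 24.0 * eps * (2.0 * s12 - s6) * inv_r2
            l = lam[ti, tj]
            if r2 < TWO_1_3 * sigma2[ti, tj]:
                e += ulj + (1.0 - l) * eps - l * lj_shift[ti, tj]
                fr += flj
            else:
                e += l * (ulj - lj_shift[ti, tj])
                fr += l * flj
        q = qq[ti, tj]
        if q != 0.0 and r2 < rc_elec2:
            inv_r = np.sqrt(inv_r2)
            ed = q * inv_r * np.exp(-kappa * r2 * inv_r)
            e += ed - dh_shift[ti, tj]
            fr += ed * (inv_r2 + kappa * inv_r)
        epot += e
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fx * dx
        wyy += fy * dy
        wzz += fz * dz
    return epot, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def max_displacement2(pos, pos0, box):
    """Largest squared minimum-image displacement since the last rebuild."""
    best = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - pos0[i, 0]
        dy = pos[i, 1] - pos0[i, 1]
        dz = pos[i, 2] - pos0[i, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best


@njit(cache=True, fastmath=True)
def bonded(pos, box, bonds, k, r0, forces):
    epot = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 0.1:
            r = 0.1
        epot += 0.5 * k * (r - r0) ** 2
        fr = -k * (r - r0) / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
        wxx += fr * dx * dx
        wyy += fr * dy * dy
        wzz += fr * dz * dz
    return epot, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def contact_counts(pos, box, types, mol_id, species_code, olig_mask,
                   sigma2, factor2, rc2):
    """Inter-molecular contact counts for the bond-ratio observable.

    A contact is an inter-molecular K/E bead pair with r² < factor²·σ_ij².
    Returns (heterotypic, homotypic) counts for beads of the oligomerized
    species (olig_mask selects its polyampholyte beads).
    """
    n = pos.shape[0]
    het = 0
    hom = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            if not (olig_mask[i] or olig_mask[j]):
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc2:
                continue
            if r2 < factor2 * sigma2[types[i], types[j]]:
                if species_code[i] == species_code[j]:
                    if olig_mask[i] and olig_mask[j]:
                        hom += 1
                else:
                    het += 1
    return het, hom
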