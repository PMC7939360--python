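"""Numba kernels for the pairwise force/energy loops.

Both potentials are shifted to zero at their cutoff so forces are
continuous there. Minimum-image convention matches
``forcefield.minimum_image`` (component in (-edge/2, edge/2]).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _min_image_comp(d: float, edge: float) -> float:
    return d - edge * np.ceil(d / edge - 0.5)


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, pairs, charges, eps, sigma, rc_lj, dh_pref, kappa,
                rc_dh, do_dh):
    """Nonbonded forces and energies over a precomputed pair list.

    Returns (forces (N,3), E_lj, E_dh).
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_lj = 0.0
    e_dh = 0.0
    # cutoff-shift constants
    sr6c = (sigma / rc_lj) ** 6
    lj_shift = 4.0 * eps * (sr6c * sr6c - sr6c)
    dh_shift = np.exp(-kappa * rc_dh) / rc_dh
    rc_lj2 = rc_lj * rc_lj
    rc_dh2 = rc_dh * rc_dh
    rc_max2 = max(rc_lj2, rc_dh2)
    sigma2 = sigma * sigma
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    eps4 = 4.0 * eps
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dx -= box[0] * np.floor(dx * ibx + 0.5)
        dy = pos[j, 1] - pos[i, 1]
        dy -= box[1] * np.floor(dy * iby + 0.5)
        dz = pos[j, 2] - pos[i, 2]
        dz -= box[2] * np.floor(dz * ibz + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rc_max2 or r2 <= 0.0:
            continue  # skin pairs beyond the cutoff; r2=0 guarded upstream
        r2inv = 1.0 / r2
        c = 0.0  # force coefficient: F_j = c * d, with d = r_j - r_i
        if r2 <= rc_lj2:
            sr2 = sigma2 * r2inv
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e_lj += eps4 * (sr12 - sr6) - lj_shift
            c += eps4 * (12.0 * sr12 - 6.0 * sr6) * r2inv
        if do_dh and r2 <= rc_dh2:
            qq = charges[i] * charges[j]
            if qq != 0.0:
                r = np.sqrt(r2)
                ex = np.exp(-kappa * r)
                e_dh += dh_pref * qq * (ex / r - dh_shift)
                # -dV/dr = pref qq e^{-kr} (k r + 1)/r^2
                c += dh_pref * qq * ex * (kappa * r + 1.0) * r2inv / r
        if c != 0.0:
            f[j, 0] += c * dx
            f[j, 1] += c * dy
            f[j, 2] += c * dz
            f[i, 0] -= c * dx
            f[i, 1] -= c * dy
            f[i, 2] -= c * dz
    return f, e_lj, e_dh


@njit(cache=True, fastmath=True)
def bond_forces(pos, box, bonds, k_bond, a):
    """Harmonic bond forces and energy: V = 0.5 k (r - a)^2 per bond."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = _min_image_comp(pos[j, 0] - pos[i, 0], box[0])
        dy = _min_image_comp(pos[j, 1] - pos[i, 1], box[1])
        dz = _min_image_comp(pos[j, 2] - pos[i, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        e += 0.5 * k_bond * (r - a) ** 2
        c = -k_bond * (r - a) / r
        f[j, 0] += c * dx
        f[j, 1] += c * dy
        f[j, 2] += c * dz
        f[i, 0] -= c * dx
        f[i, 1] -= c * dy
        f[i, 2] -= c * dz
    return f, e


@njit(cache=True, fastmath=True)
def max_displacement(pos, ref, box):
    """Largest minimum-image displacement magnitude between two snapshots."""
    best = 0.0
    for i in range(pos.shape[0]):
        dx = _min_image_comp(pos[i, 0] - ref[i, 0], box[0])
        dy = _min_image_comp(pos[i, 1] - ref[i, 1], box[1])
        dz = _min_image_comp(pos[i, 2] - ref[i, 2], box[2])
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > best:
            best = d
    return best
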