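"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (O(L^2) / O(N^2) double loops,
central finite differences) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def scd_double_loop(charges) -> float:
    """Naive O(L^2) sequence charge decoration."""
    q = list(charges)
    L = len(q)
    total = 0.0
    for i in range(L):
        for j in range(i + 1, L):
            total += q[i] * q[j] * math.sqrt(j - i)
    return total / L


def min_image(d, box):
    d = np.asarray(d, dtype=float)
    return d - box * np.ceil(d / box - 0.5)


def lj_shifted(r, eps, sigma, rc):
    if r > rc:
        return 0.0

    def raw(x):
        s6 = (sigma / x) ** 6
        return 4.0 * eps * (s6 * s6 - s6)

    return raw(r) - raw(rc)


def dh_shifted(qq, r, pref, kappa, rc):
    if qq == 0 or r > rc or pref == 0.0:
        return 0.0
    return pref * qq * (math.exp(-kappa * r) / r - math.exp(-kappa * rc) / rc)


def brute_energy(config, topology, params):
    """(E_bond, E_lj, E_dh) by an O(N^2) double loop with minimum image."""
    pos = config.positions
    box = config.box
    n = pos.shape[0]
    bonded = {tuple(sorted(map(int, b))) for b in topology.bonds}
    e_lj = e_dh = 0.0
    pref = params.dh_prefactor
    kappa = params.kappa
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            r = float(np.linalg.norm(min_image(pos[j] - pos[i], box)))
            e_lj += lj_shifted(r, params.eps_lj, params.sigma_lj, params.r_cut_lj)
            if not params.screened:
                qq = int(topology.charges[i]) * int(topology.charges[j])
                e_dh += dh_shifted(qq, r, pref, kappa, params.r_cut_dh)
    e_bond = 0.0
    for i, j in topology.bonds:
        r = float(np.linalg.norm(min_image(pos[j] - pos[i], box)))
        e_bond += 0.5 * params.k_bond * (r - params.a) ** 2
    return e_bond, e_lj, e_dh


def brute_neighbor_pairs(config, cutoff, topology=None, exclude_bonded=True):
    """All unordered pairs with minimum-image distance <= cutoff."""
    pos = config.positions
    box = config.box
    n = pos.shape[0]
    bonded = set()
    if exclude_bonded and topology is not None:
        bonded = {tuple(sorted(map(int, b))) for b in topology.bonds}
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            r = float(np.linalg.norm(min_image(pos[j] - pos[i], box)))
            if r <= cutoff:
                out.append((i, j))
    return sorted(out)


def brute_contacts(config, topology, cutoff):
    """Per-chain opposite-charge contact counts by double loop."""
    pos = config.positions
    box = config.box
    n = pos.shape[0]
    chain = topology.chain_of_bead
    q = topology.charges
    e_intra = np.zeros(topology.n_chains, dtype=int)
    e_inter = np.zeros(topology.n_chains, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if q[i] * q[j] != -1:
                continue
            r = float(np.linalg.norm(min_image(pos[j] - pos[i], box)))
            if r < cutoff:
                if chain[i] == chain[j]:
                    e_intra[chain[i]] += 1
                else:
                    e_inter[chain[i]] += 1
                    e_inter[chain[j]] += 1
    return e_intra, e_inter


def fd_forces(config, topology, params, h=1e-6):
    """Central finite differences of the total energy."""
    from idrslab.forcefield import Configuration, total_energy

    pos = config.positions
    out = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for k in range(3):
            for sgn, slot in ((1, 0), (-1, 1)):
                p = pos.copy()
                p[i, k] += sgn * h
                e = total_energy(
                    Configuration(p, config.box), topology, params
                ).total
                if slot == 0:
                    e_plus = e
                else:
                    e_minus = e
            out[i, k] = -(e_plus - e_minus) / (2.0 * h)
    return out
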