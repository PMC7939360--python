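"""Potential energy function of the slab model.

Harmonic bonds, 12-6 Lennard-Jones pair interactions and Debye-Hueckel
screened electrostatics under periodic minimum-image geometry. All
internal units: nm, kJ/mol, elementary charge, ps, g/mol.

Conventions
-----------
* LJ form is the standard 4*eps*[(sigma/r)^12 - (sigma/r)^6]; eps is
  the well depth (minimum -eps at r = 2^(1/6) sigma).
* Both nonbonded potentials are shifted so they vanish continuously at
  their cutoff.
* Only directly bonded (1-2) pairs are excluded from nonbonded terms.
* ``C_salt=None`` is the "screened" sentinel: the electrostatic term is
  exactly zero (infinitely strong screening), not a numerical limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels

#: electric conversion factor, kJ mol^-1 nm e^-2
K_COULOMB = 138.94

#: minimum tolerated nonbonded distance before total_energy refuses, nm
HARD_FLOOR = 1e-3

SCREENED = "screened"


def debye_kappa(c_salt: float) -> float:
    """Inverse Debye screening length, nm^-1: kappa = 3.2 * sqrt(C_salt in M)."""
    if c_salt < 0:
        raise ValueError("salt concentration must be non-negative")
    return 3.2 * float(np.sqrt(c_salt))


@dataclass
class ModelParams:
    """Force-field and solvent parameters.

    ``c_salt`` is the molar salt concentration, or ``None`` / the string
    ``"screened"`` for fully screened electrostatics.
    """

    a: float = 0.38                 # mean bond length, nm
    sigma_lj: float = 1.0           # LJ finite distance, nm
    eps_lj: float = 0.01            # LJ well depth, kJ/mol
    # Stiff enough that RMS bond-length fluctuation < 3% of a at 4.0 T_0
    # (equipartition alone needs k > kB*T/(0.03 a)^2 ~ 2.6e4; 1-3 LJ
    # repulsion inflates the fluctuation further, hence the margin).
    k_bond: float = 50000.0         # kJ/mol/nm^2
    k_coulomb: float = K_COULOMB
    dielectric: float = 80.0
    c_salt: Optional[float] = 0.01  # M; None => screened
    use_ion_size_b: bool = False    # B(kappa) = exp(kappa d)/(1 + kappa d) if set
    ion_diameter: float = 0.4       # nm, only used with use_ion_size_b
    r_cut_lj: float = 3.0           # nm (= 3 sigma)
    r_cut_dh: float = 3.0           # nm
    bead_mass: float = 110.0        # g/mol (average residue)

    def __post_init__(self) -> None:
        if isinstance(self.c_salt, str):
            if self.c_salt != SCREENED:
                raise ValueError(f"unknown salt mode {self.c_salt!r}")
            self.c_salt = None
        for name in ("a", "sigma_lj", "r_cut_lj", "r_cut_dh", "bead_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def screened(self) -> bool:
        return self.c_salt is None

    @property
    def kappa(self) -> float:
        """Inverse Debye length, nm^-1 (0 in screened mode, unused there)."""
        return 0.0 if self.screened else debye_kappa(self.c_salt)

    @property
    def b_kappa(self) -> float:
        """Salt-dependent coefficient B(kappa); 1 by default."""
        if self.screened or not self.use_ion_size_b:
            return 1.0
        kd = self.kappa * self.ion_diameter
        return float(np.exp(kd) / (1.0 + kd))

    @property
    def dh_prefactor(self) -> float:
        """K_coulomb * B(kappa) / dielectric; 0 in screened mode."""
        if self.screened:
            return 0.0
        return self.k_coulomb * self.b_kappa / self.dielectric

    def validate_box(self, box: np.ndarray) -> None:
        half = 0.5 * float(np.min(box))
        if self.r_cut_lj > half or self.r_cut_dh > half:
            raise ValueError(
                f"cutoffs ({self.r_cut_lj}, {self.r_cut_dh}) exceed half the "
                f"smallest box edge ({half})"
            )


@dataclass
class Topology:
    """n identical chains of L beads each; bonds join consecutive beads."""

    n_chains: int
    chain_length: int
    charges: np.ndarray = field(repr=False)
    bonds: np.ndarray = field(repr=False)

    @classmethod
    def from_charges(cls, chain_charges: np.ndarray, n_chains: int) -> "Topology":
        chain_charges = np.asarray(chain_charges, dtype=np.int64)
        L = len(chain_charges)
        charges = np.tile(chain_charges, n_chains)
        bonds = []
        for c in range(n_chains):
            off = c * L
            for i in range(L - 1):
                bonds.append((off + i, off + i + 1))
        bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
        return cls(n_chains=n_chains, chain_length=L, charges=charges, bonds=bonds)

    @classmethod
    def from_sequence(cls, seq, n_chains: int) -> "Topology":
        return cls.from_charges(seq.charges, n_chains)

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length

    @property
    def chain_of_bead(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain_length)

    def bead_range(self, chain: int) -> slice:
        L = self.chain_length
        return slice(chain * L, (chain + 1) * L)


@dataclass
class Configuration:
    """Bead positions in a fully periodic rectangular box."""

    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> np.ndarray:
        """Positions mapped into [0, box) componentwise."""
        return self.positions - self.box * np.floor(self.positions / self.box)

    def unwrap_chains(self, topology: Topology) -> np.ndarray:
        """Per-chain unwrapped coordinates (bonds never cross an image)."""
        pos = self.positions
        out = pos.copy()
        L = topology.chain_length
        for c in range(topology.n_chains):
            s = c * L
            for i in range(s + 1, s + L):
                d = minimum_image(pos[i] - out[i - 1], self.box)
                out[i] = out[i - 1] + d
        return out

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.box.copy())


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map each displacement component into (-edge/2, edge/2]."""
    displacement = np.asarray(displacement, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return displacement - box * np.ceil(displacement / box - 0.5)


def lj_pair_energy(r: float, params: ModelParams, shifted: bool = True) -> float:
    """4 eps [(sigma/r)^12 - (sigma/r)^6], cut (and by default shifted) at r_cut_lj."""
    if r <= 0:
        raise ValueError("overlapping beads: r must be positive")
    if r > params.r_cut_lj:
        return 0.0
    e = _lj_raw(r, params.eps_lj, params.sigma_lj)
    if shifted:
        e -= _lj_raw(params.r_cut_lj, params.eps_lj, params.sigma_lj)
    return e


def _lj_raw(r: float, eps: float, sigma: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def dh_pair_energy(
    q_i: float, q_j: float, r: float, params: ModelParams, shifted: bool = True
) -> float:
    """Debye-Hueckel pair energy K B(kappa) q_i q_j exp(-kappa r)/(eps r).

    Exactly zero in screened mode, for neutral beads, or beyond r_cut_dh.
    """
    qq = q_i * q_j
    if params.screened or qq == 0:
        return 0.0
    if r <= 0:
        raise ValueError("overlapping charged beads: r must be positive")
    if r > params.r_cut_dh:
        return 0.0
    kappa = params.kappa
    e = params.dh_prefactor * qq * np.exp(-kappa * r) / r
    if shifted:
        rc = params.r_cut_dh
        e -= params.dh_prefactor * qq * np.exp(-kappa * rc) / rc
    return float(e)


def bond_energy(r: float, params: ModelParams) -> float:
    """Harmonic bond: 0.5 k (r - a)^2."""
    if r < 0:
        raise ValueError("negative bond length")
    return 0.5 * params.k_bond * (r - params.a) ** 2


def neighbor_pairs(
    config: Configuration,
    cutoff: float,
    topology: Optional[Topology] = None,
    exclude_bonded: bool = True,
) -> np.ndarray:
    """Unordered bead pairs with minimum-image distance <= cutoff.

    Directly bonded (1-2) pairs are excluded when a topology is given.
    Returns an (M, 2) int array with i < j, lexicographically sorted.
    """
    box = config.box
    if cutoff > 0.5 * float(np.min(box)):
        raise ValueError("cutoff exceeds half the smallest box edge")
    wrapped = config.wrapped()
    # cKDTree requires coordinates strictly inside [0, boxsize)
    wrapped = np.minimum(wrapped, np.nextafter(box, -np.inf))
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    if exclude_bonded and topology is not None and topology.bonds.size:
        n = config.n_beads
        bonds = np.sort(topology.bonds, axis=1)
        bond_keys = bonds[:, 0].astype(np.int64) * n + bonds[:, 1]
        pair_keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
        pairs = pairs[~np.isin(pair_keys, bond_keys)]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return np.ascontiguousarray(pairs[order], dtype=np.int64)


class EnergyBreakdown(NamedTuple):
    bond: float
    lj: float
    dh: float

    @property
    def total(self) -> float:
        return self.bond + self.lj + self.dh


def _kernel_args(params: ModelParams):
    return (
        params.eps_lj,
        params.sigma_lj,
        params.r_cut_lj,
        params.dh_prefactor,
        params.kappa,
        params.r_cut_dh,
        not params.screened,
    )


def _nonbonded_pairs(config: Configuration, topology: Topology, params: ModelParams):
    cutoff = max(params.r_cut_lj, params.r_cut_dh)
    return neighbor_pairs(config, cutoff, topology, exclude_bonded=True)


def total_energy(
    config: Configuration, topology: Topology, params: ModelParams
) -> EnergyBreakdown:
    """Bond, LJ and DH components (kJ/mol) via minimum image and cutoffs."""
    params.validate_box(config.box)
    pairs = _nonbonded_pairs(config, topology, params)
    pos = config.positions
    if pairs.size:
        d = minimum_image(pos[pairs[:, 1]] - pos[pairs[:, 0]], config.box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < HARD_FLOOR):
            k = int(np.argmin(r))
            raise ValueError(
                f"overlapping nonbonded beads {pairs[k, 0]} and {pairs[k, 1]} "
                f"(r = {r[k]:.2e} nm)"
            )
    _, e_lj, e_dh = _kernels.pair_forces(
        pos, config.box, pairs, np.asarray(topology.charges, dtype=np.float64),
        *_kernel_args(params)
    )
    _, e_bond = _kernels.bond_forces(
        pos, config.box, topology.bonds, params.k_bond, params.a
    )
    return EnergyBreakdown(bond=float(e_bond), lj=float(e_lj), dh=float(e_dh))


def forces(
    config: Configuration, topology: Topology, params: ModelParams
) -> np.ndarray:
    """Analytic forces F = -grad E, kJ/mol/nm, shape (N, 3)."""
    params.validate_box(config.box)
    pairs = _nonbonded_pairs(config, topology, params)
    pos = config.positions
    f_nb, _, _ = _kernels.pair_forces(
        pos, config.box, pairs, np.asarray(topology.charges, dtype=np.float64),
        *_kernel_args(params)
    )
    f_b, _ = _kernels.bond_forces(
        pos, config.box, topology.bonds, params.k_bond, params.a
    )
    return f_nb + f_b
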