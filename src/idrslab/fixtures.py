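"""Seeded synthetic inputs with known ground truth.

Planted slab configurations (a dense block of chains plus a dilute gas
at chosen densities), charged ideal gases for contact/rdf oracles, and
order-parameter series drawn from the critical scaling law — so every
analysis statistic can be tested without running dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import Configuration, Topology
from .slab_analysis import DensityProfile


@dataclass
class PlantedSlabSpec:
    n_chains: int
    chain_length: int
    box: tuple                      # (x, y, z) nm
    condensed_fraction: float       # phi_c, fraction of chains in the slab
    half_width: float               # w, nm; slab occupies |z - z_c| < w
    dilute_jitter_sd: float = 0.0
    condensed_mode: str = "compact-coil"
    dilute_mode: str = "extended"
    coil_radius: float = 1.5        # nm, confinement sphere for compact coils
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.condensed_fraction <= 1.0:
            raise ValueError("condensed fraction must be in [0, 1]")
        if 2.0 * self.half_width >= self.box[2]:
            raise ValueError("slab wider than the box")


def _coil(rng, length: int, center: np.ndarray, radius: float, a: float = 0.38):
    """Bond-respecting random walk confined to a sphere around *center*."""
    pos = np.empty((length, 3))
    pos[0] = center
    for i in range(1, length):
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pos[i - 1] + a * u
            if np.linalg.norm(cand - center) <= radius:
                pos[i] = cand
                break
        else:  # pragma: no cover - radius >= a always admits a step inward
            raise RuntimeError("coil confinement too tight")
    return pos


def _extended(rng, length: int, center: np.ndarray, a: float = 0.38,
              wobble: float = 0.15):
    """Near-straight walk: fixed random axis with small angular jitter."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    pos = np.empty((length, 3))
    pos[0] = center - 0.5 * (length - 1) * a * axis
    for i in range(1, length):
        step = axis + wobble * rng.normal(size=3)
        step /= np.linalg.norm(step)
        pos[i] = pos[i - 1] + a * step
    return pos


def expected_profile(spec: PlantedSlabSpec, n_windows: int = 30) -> np.ndarray:
    """Closed-form expected P_gamma for a planted slab (chains as points).

    Condensed chain centers are uniform on [z_c - w, z_c + w] with z_c the
    box middle; dilute centers uniform on the complement. The expected
    window fraction is the overlap of each window with the two regions,
    weighted by phi_c and 1 - phi_c.
    """
    box_z = spec.box[2]
    zc = 0.5 * box_z
    lo, hi = zc - spec.half_width, zc + spec.half_width
    edges = np.linspace(0.0, box_z, n_windows + 1)
    p = np.zeros(n_windows)
    dense_len = hi - lo
    dilute_len = box_z - dense_len
    for k in range(n_windows):
        a, b = edges[k], edges[k + 1]
        ov = max(0.0, min(b, hi) - max(a, lo))
        p[k] = spec.condensed_fraction * (ov / dense_len if dense_len else 0.0)
        p[k] += (1.0 - spec.condensed_fraction) * ((b - a - ov) / dilute_len
                                                   if dilute_len else 0.0)
    return p


def make_planted_slab(
    spec: PlantedSlabSpec, n_windows: int = 30
) -> tuple[Topology, Configuration, DensityProfile]:
    """Planted two-phase configuration plus its analytic expected profile."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    zc = 0.5 * box[2]
    n_cond = int(round(spec.condensed_fraction * spec.n_chains))
    L = spec.chain_length
    positions = np.empty((spec.n_chains * L, 3))
    for c in range(spec.n_chains):
        condensed = c < n_cond
        center = np.array([
            rng.uniform(0, box[0]),
            rng.uniform(0, box[1]),
            0.0,
        ])
        if condensed:
            center[2] = rng.uniform(zc - spec.half_width, zc + spec.half_width)
            mode = spec.condensed_mode
        else:
            # uniform over the complement of the slab
            gap = box[2] - 2.0 * spec.half_width
            u = rng.uniform(0, gap)
            center[2] = (zc + spec.half_width + u) % box[2]
            if spec.dilute_jitter_sd:
                center[2] = (center[2] + rng.normal(0, spec.dilute_jitter_sd)) % box[2]
            mode = spec.dilute_mode
        if L == 1:
            chain = center[None, :]
        elif mode == "compact-coil":
            chain = _coil(rng, L, center, spec.coil_radius)
        elif mode == "extended":
            chain = _extended(rng, L, center)
        else:
            raise ValueError(f"unknown conformation mode {mode!r}")
        # re-center the walk so the chain CM sits at the drawn center
        chain = chain - chain.mean(axis=0) + center
        positions[c * L : (c + 1) * L] = chain
    topo = Topology.from_charges(np.zeros(L, dtype=np.int64), spec.n_chains)
    config = Configuration(positions, box)
    exp_p = expected_profile(spec, n_windows)
    wl = box[2] / n_windows
    n = spec.n_chains * L
    profile = DensityProfile(
        m_gamma=np.round(exp_p * n).astype(np.int64),
        p_gamma=exp_p,
        window_length=wl,
        d_gamma=exp_p * n / (box[0] * box[1] * wl),
    )
    return topo, config, profile


def make_charged_gas(
    n_beads: int,
    box,
    pattern: str = "alternating",
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> tuple[Topology, Configuration]:
    """Uniform random gas of single-bead chains with the given charge pattern.

    pattern: ``alternating`` (+1/-1/...), ``random`` (seeded +-1), or
    ``neutral``. Pass *positions* to override the random placement (used
    by hand-constructed oracle cases).
    """
    if n_beads < 2:
        raise ValueError("need at least two beads")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if pattern == "alternating":
        charges = np.array([1 if i % 2 == 0 else -1 for i in range(n_beads)])
    elif pattern == "random":
        charges = rng.choice([-1, 1], size=n_beads)
    elif pattern == "neutral":
        charges = np.zeros(n_beads, dtype=np.int64)
    else:
        raise ValueError(f"unknown charge pattern {pattern!r}")
    if positions is None:
        positions = rng.uniform(0, 1, size=(n_beads, 3)) * box
    topo = Topology(
        n_chains=n_beads,
        chain_length=1,
        charges=charges.astype(np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
    )
    return topo, Configuration(np.asarray(positions, dtype=float), box)


def make_order_parameter_series(
    amplitude: float,
    t_cr: float,
    beta: float,
    temperatures,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(T, order parameter) series from A (T_cr - T)^beta, floored at zero."""
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        v = amplitude * (t_cr - t) ** beta if t < t_cr else 0.0
        if noise_sd:
            v += rng.normal(0.0, noise_sd)
        out.append((float(t), max(0.0, float(v))))
    return out
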