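"""System construction, energy minimization and Langevin dynamics.

Reduced units: temperatures are multiples of T_0 (nominally 100 K,
k_B*T_0 = 0.83145 kJ/mol); the bookkeeping time unit tau is 1 ns
(500,000 steps at dt = 2 fs). Internal units nm / ps / kJ/mol / g/mol.

The dense starting block is produced by deterministic packing plus
minimization instead of an NPT compaction stage; this protocol
deviation is logged whenever a packed system is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import _kernels
from .forcefield import (
    Configuration,
    ModelParams,
    Topology,
    neighbor_pairs,
)

logger = logging.getLogger(__name__)

#: k_B * T_0 in kJ/mol for T_0 = 100 K
KB_T0 = 0.83145
#: steps per bookkeeping unit tau (1 ns at dt = 2 fs)
STEPS_PER_TAU = 500_000
#: tau in ps
TAU_PS = 1000.0


def kbt(temperature_t0: float) -> float:
    """Thermal energy k_B*T in kJ/mol for a temperature in T_0 units."""
    if temperature_t0 <= 0:
        raise ValueError("temperature must be positive")
    return KB_T0 * temperature_t0


@dataclass
class SimSchedule:
    """Langevin run schedule; temperature in T_0 units, dt in ps."""

    temperature: float
    n_steps: int
    dt: float = 0.002          # 2 fs
    friction: float = 1.0      # ps^-1
    seed: int = 0
    snapshot_interval: int = 10_000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction < 0 or self.temperature <= 0:
            raise ValueError("invalid schedule")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")


@dataclass
class SimState:
    """Mutable integrator state; serializable so runs resume bit-exactly."""

    config: Configuration
    velocities: np.ndarray
    step: int
    rng: np.random.Generator

    @classmethod
    def new(
        cls,
        config: Configuration,
        topology: Topology,
        params: ModelParams,
        schedule: SimSchedule,
    ) -> "SimState":
        """Fresh state with Maxwell-Boltzmann velocities at the run temperature."""
        rng = np.random.default_rng(schedule.seed)
        sigma_v = np.sqrt(kbt(schedule.temperature) / params.bead_mass)
        v = rng.normal(0.0, sigma_v, size=config.positions.shape)
        return cls(config=config.copy(), velocities=v, step=0, rng=rng)

    def to_dict(self) -> dict:
        return {
            "positions": self.config.positions.copy(),
            "box": self.config.box.copy(),
            "velocities": self.velocities.copy(),
            "step": self.step,
            "rng_state": self.rng.bit_generator.state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimState":
        rng = np.random.default_rng()
        rng.bit_generator.state = d["rng_state"]
        return cls(
            config=Configuration(d["positions"].copy(), d["box"].copy()),
            velocities=d["velocities"].copy(),
            step=int(d["step"]),
            rng=rng,
        )


@dataclass
class Trajectory:
    """Time-ordered periodic-box configurations with step/tau stamps."""

    frames: list = field(default_factory=list)      # (N, 3) arrays, nm
    steps: list = field(default_factory=list)
    box: Optional[np.ndarray] = None
    dt: float = 0.002

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_tau(self) -> np.ndarray:
        return np.asarray(self.steps, dtype=float) * self.dt / TAU_PS

    def append(self, positions: np.ndarray, step: int) -> None:
        self.frames.append(positions.copy())
        self.steps.append(int(step))

    def configuration(self, frame: int) -> Configuration:
        return Configuration(self.frames[frame].copy(), self.box.copy())


def build_packed_system(
    topology: Topology,
    target_box,
    seed: int = 0,
    min_separation: float = 0.45,
    max_chain_restarts: int = 200,
) -> Configuration:
    """Place all chains as self-avoiding-ish random walks in a compact region.

    Chains are grown with fixed bond length ``a`` (taken as 0.38 nm) inside
    a cubic region with the requested x,y footprint, rejecting beads closer
    than *min_separation* to anything already placed. Deterministic per seed.
    """
    logger.info(
        "protocol deviation: dense packing by seeded random walks replaces "
        "the NPT compaction stage"
    )
    box = np.asarray(target_box, dtype=np.float64)
    a = 0.38
    rng = np.random.default_rng(seed)
    region = np.array([box[0], box[1], min(box[0], box[1], box[2])])
    n, L = topology.n_chains, topology.chain_length
    placed = np.empty((n * L, 3))
    n_placed = 0
    from scipy.spatial import cKDTree

    tree = None
    for c in range(n):
        for restart in range(max_chain_restarts):
            chain = np.empty((L, 3))
            chain[0] = rng.uniform(0, 1, 3) * region
            ok = True
            for i in range(1, L):
                for attempt in range(60):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    cand = chain[i - 1] + a * u
                    cand_w = cand - region * np.floor(cand / region)
                    # keep inside the compact region (non-periodic growth)
                    if np.any(cand < 0) or np.any(cand > region):
                        continue
                    d_prev = np.linalg.norm(
                        chain[max(0, i - 6) : i - 1] - cand, axis=1
                    )
                    if d_prev.size and d_prev.min() < min_separation:
                        continue
                    if tree is not None:
                        if tree.query_ball_point(cand_w, min_separation):
                            continue
                    chain[i] = cand
                    break
                else:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"failed to place chain {c}; try a larger box or smaller "
                f"min_separation"
            )
        placed[n_placed : n_placed + L] = chain
        n_placed += L
        pts = placed[:n_placed] - region * np.floor(placed[:n_placed] / region)
        pts = np.minimum(pts, np.nextafter(region, -np.inf))
        tree = cKDTree(pts, boxsize=region)
    # center the compact block inside the target box
    placed[:, 2] += 0.5 * (box[2] - region[2])
    return Configuration(placed, box)


def elongate_box(config: Configuration, z_new: float = 300.0) -> Configuration:
    """Grow the box along z, re-centering the dense block at z = 0."""
    if z_new < config.box[2]:
        raise ValueError("z_new must not be smaller than the current z edge")
    new_box = config.box.copy()
    new_box[2] = z_new
    pos = config.positions.copy()
    # circular mean of z on the old box, so a block straddling the boundary
    # is still centered correctly
    theta = 2.0 * np.pi * pos[:, 2] / config.box[2]
    zc = (config.box[2] / (2.0 * np.pi)) * np.angle(
        np.mean(np.exp(1j * theta))
    )
    pos[:, 2] -= zc
    return Configuration(pos, new_box)


def minimize(
    config: Configuration,
    topology: Topology,
    params: ModelParams,
    max_steps: int = 500,
    tol: float = 10.0,
    initial_step: float = 0.01,
) -> Configuration:
    """Steepest descent with backtracking; energy is monotonically non-increasing.

    Stops when the largest per-bead force magnitude drops below *tol*
    (kJ/mol/nm) or after *max_steps* iterations.
    """
    params.validate_box(config.box)
    cfg = config.copy()
    charges = np.asarray(topology.charges, dtype=np.float64)
    from .forcefield import _kernel_args

    kargs = _kernel_args(params)
    nlist = _NeighborList(topology, params, skin=0.4)

    def eval_ef(c: Configuration):
        pairs = nlist.update(c)
        f, e_lj, e_dh = _kernels.pair_forces(c.positions, c.box, pairs, charges, *kargs)
        fb, e_bond = _kernels.bond_forces(
            c.positions, c.box, topology.bonds, params.k_bond, params.a
        )
        return f + fb, e_bond + e_lj + e_dh

    f, e = eval_ef(cfg)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at minimization entry")
    alpha = initial_step
    for _ in range(max_steps):
        fmax = float(np.max(np.linalg.norm(f, axis=1)))
        if fmax < tol:
            break
        direction = f / fmax  # normalized so alpha is a displacement in nm
        accepted = False
        for _ in range(30):
            trial = Configuration(cfg.positions + alpha * direction, cfg.box)
            f_trial, e_trial = eval_ef(trial)
            if np.isfinite(e_trial) and e_trial <= e:
                cfg, e, f = trial, e_trial, f_trial
                alpha = min(alpha * 1.2, 0.1)
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return cfg


class _NeighborList:
    """Verlet list with a skin; rebuilt when displacements exceed skin/2."""

    def __init__(self, topology: Topology, params: ModelParams, skin: float = 0.3):
        self.cutoff = max(params.r_cut_lj, params.r_cut_dh)
        self.skin = skin
        self.topology = topology
        self.pairs = None
        self.ref = None

    def update(self, config: Configuration, force_rebuild: bool = False) -> np.ndarray:
        if (
            force_rebuild
            or self.pairs is None
            or _kernels.max_displacement(config.positions, self.ref, config.box)
            > 0.5 * self.skin
        ):
            self.pairs = neighbor_pairs(
                config, self.cutoff + self.skin, self.topology, exclude_bonded=True
            )
            self.ref = config.positions.copy()
        return self.pairs


def run_langevin(
    state: SimState,
    topology: Topology,
    params: ModelParams,
    schedule: SimSchedule,
    trajectory: Optional[Trajectory] = None,
    log_interval: int = 0,
) -> Trajectory:
    """BAOAB-splitting Langevin dynamics in the NVT ensemble.

    Mutates *state* in place and returns the (possibly continued)
    trajectory. Snapshots are recorded at entry and every
    ``schedule.snapshot_interval`` steps. Bit-reproducible for a fixed
    state (seeded rng lives on the state, so checkpoint/resume matches
    an uninterrupted run exactly).
    """
    params.validate_box(state.config.box)
    if trajectory is None:
        trajectory = Trajectory(box=state.config.box.copy(), dt=schedule.dt)
        trajectory.append(state.config.positions, state.step)
    if schedule.n_steps == 0:
        return trajectory

    dt = schedule.dt
    m = params.bead_mass
    kT = kbt(schedule.temperature)
    gamma = schedule.friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(kT / m)
    charges = np.asarray(topology.charges, dtype=np.float64)
    from .forcefield import _kernel_args

    kargs = _kernel_args(params)
    nlist = _NeighborList(topology, params)
    pos = state.config.positions
    vel = state.velocities
    box = state.config.box
    max_step_disp = float(np.min(box))

    pairs = nlist.update(state.config, force_rebuild=True)
    f, _, _ = _kernels.pair_forces(pos, box, pairs, charges, *kargs)
    fb, _ = _kernels.bond_forces(pos, box, topology.bonds, params.k_bond, params.a)
    f = f + fb

    for _ in range(schedule.n_steps):
        vel += (0.5 * dt / m) * f
        dx1 = 0.5 * dt * vel
        pos += dx1
        vel *= c1
        vel += c2 * state.rng.normal(size=vel.shape)
        dx2 = 0.5 * dt * vel
        pos += dx2
        disp = float(np.max(np.abs(dx1) + np.abs(dx2)))
        if not np.isfinite(disp) or disp > max_step_disp:
            raise RuntimeError(
                f"numeric blow-up at step {state.step}: per-step displacement "
                f"{disp:.3g} nm exceeds the box edge"
            )
        pairs = nlist.update(state.config)
        f, e_lj, e_dh = _kernels.pair_forces(pos, box, pairs, charges, *kargs)
        fb, e_bond = _kernels.bond_forces(
            pos, box, topology.bonds, params.k_bond, params.a
        )
        f = f + fb
        vel += (0.5 * dt / m) * f
        state.step += 1
        if log_interval and state.step % log_interval == 0:
            ke = 0.5 * m * float(np.sum(vel * vel))
            t_kin = 2.0 * ke / (3.0 * pos.shape[0] * KB_T0)
            z = pos[:, 2] - box[2] * np.floor(pos[:, 2] / box[2])
            counts, _ = np.histogram(z, bins=30, range=(0.0, box[2]))
            ph_pl = (counts.max() - counts.min()) / pos.shape[0]
            logger.debug(
                "step %d E_bond=%.4g E_lj=%.4g E_dh=%.4g T_kin=%.3f T0 "
                "PH-PL=%.3f",
                state.step, e_bond, e_lj, e_dh, t_kin, ph_pl,
            )
        if state.step % schedule.snapshot_interval == 0:
            trajectory.append(pos, state.step)
    if trajectory.steps[-1] != state.step:
        trajectory.append(pos, state.step)
    return trajectory


def kinetic_temperature(state: SimState, params: ModelParams) -> float:
    """Instantaneous kinetic temperature in T_0 units (equipartition)."""
    ke = 0.5 * params.bead_mass * float(np.sum(state.velocities**2))
    return 2.0 * ke / (3.0 * state.velocities.shape[0] * KB_T0)


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(trajectory: Trajectory, path, format: str = "xyz") -> None:
    """Write a trajectory as multi-frame XYZ, PDB snapshots or a flat table.

    XYZ coordinates are in nm with the comment line carrying step, tau and
    box; PDB coordinates and CRYST1 are in Angstrom; the native table is a
    TSV with columns frame, step, tau, bead, x, y, z (nm).
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    path = Path(path)
    if format == "xyz":
        with open(path, "w") as fh:
            for k, (frame, step) in enumerate(zip(trajectory.frames, trajectory.steps)):
                tau = step * trajectory.dt / TAU_PS
                b = trajectory.box
                fh.write(f"{frame.shape[0]}\n")
                fh.write(
                    f"step={step} tau={tau:.9g} box={b[0]:.9g} {b[1]:.9g} {b[2]:.9g}\n"
                )
                for x, y, z in frame:
                    fh.write(f"CA {x:.9f} {y:.9f} {z:.9f}\n")
    elif format == "pdb-snapshots":
        b = trajectory.box * 10.0  # Angstrom
        with open(path, "w") as fh:
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for k, (frame, step) in enumerate(zip(trajectory.frames, trajectory.steps)):
                fh.write(f"MODEL     {k + 1:4d}\n")
                wrapped = frame - trajectory.box * np.floor(frame / trajectory.box)
                for i, (x, y, z) in enumerate(wrapped * 10.0):
                    serial = (i % 99999) + 1
                    fh.write(
                        f"ATOM  {serial:5d}  CA  GLY A   1    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                fh.write("ENDMDL\n")
    elif format == "native-table":
        with open(path, "w") as fh:
            fh.write("frame\tstep\ttau\tbead\tx\ty\tz\n")
            for k, (frame, step) in enumerate(zip(trajectory.frames, trajectory.steps)):
                tau = step * trajectory.dt / TAU_PS
                for i, (x, y, z) in enumerate(frame):
                    fh.write(f"{k}\t{step}\t{tau:.9g}\t{i}\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory_xyz(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` in xyz format."""
    traj = Trajectory()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        meta = dict(
            (kv.split("=", 1)[0], kv.split("=", 1)[1])
            for kv in lines[i + 1].split()
            if "=" in kv
        )
        # box holds three whitespace-separated numbers after "box="
        parts = lines[i + 1].split("box=")[1].split()
        traj.box = np.array([float(parts[0]), float(parts[1]), float(parts[2])])
        step = int(meta["step"])
        frame = np.array(
            [[float(v) for v in lines[i + 2 + k].split()[1:4]] for k in range(n)]
        )
        traj.append(frame, step)
        i += 2 + n
    return traj
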