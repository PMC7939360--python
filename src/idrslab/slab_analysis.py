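"""Trajectory statistics for slab coexistence runs.

Density profiles along z and the P_H - P_L order parameter, LLPS calling
and critical-temperature estimation, head-end distances, displacement
|z| with periodic center-of-mass mirrors, windowed reaction-coordinate
statistics, electrostatic-contact counting, chain-pair radial
distribution functions, and the packed/dispersed/fully-spread (P/D/F)
form classification.

Lengths are nm internally; head-end distance D and the displacement
reaction coordinate are reported in Angstrom in outputs to match the
conventional figure units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .forcefield import Configuration, ModelParams, Topology, minimum_image

#: LLPS is called obvious above this P_H - P_L value
LLPS_OBVIOUS = 0.15
#: LLPS is considered absent below this P_H - P_L value
LLPS_ABSENT = 0.07


# ---------------------------------------------------------------------------
# density profile and phase metric


@dataclass
class DensityProfile:
    m_gamma: np.ndarray          # bead counts per window
    p_gamma: np.ndarray          # m_gamma / N
    window_length: float         # nm
    d_gamma: Optional[np.ndarray] = None   # beads / nm^3

    def __post_init__(self) -> None:
        assert int(self.m_gamma.sum()) == round(float(self.m_gamma.sum()))


@dataclass
class PhasePoint:
    p_h: float
    p_l: float
    temperature: Optional[float] = None
    salt: Optional[object] = None
    averaging_order: str = "profile-first"

    @property
    def order_parameter(self) -> float:
        return self.p_h - self.p_l

    @property
    def llps_obvious(self) -> bool:
        return self.order_parameter > LLPS_OBVIOUS

    @property
    def llps_absent(self) -> bool:
        return self.order_parameter < LLPS_ABSENT


def density_profile(config: Configuration, n_windows: int = 30) -> DensityProfile:
    """Bead-count profile along z over *n_windows* half-open windows."""
    z = config.wrapped()[:, 2]
    box_z = float(config.box[2])
    edges = np.linspace(0.0, box_z, n_windows + 1)
    m, _ = np.histogram(z, bins=edges)
    n = config.n_beads
    wl = box_z / n_windows
    vol = float(config.box[0] * config.box[1]) * wl
    return DensityProfile(
        m_gamma=m.astype(np.int64),
        p_gamma=m / n,
        window_length=wl,
        d_gamma=m / vol,
    )


def phase_metric(
    profiles: Sequence[DensityProfile],
    temperature: Optional[float] = None,
    salt=None,
    order: str = "profile-first",
) -> PhasePoint:
    """P_H and P_L over an averaging window of frames.

    ``order="profile-first"`` (default) averages P_gamma over the frames
    and then takes max/min; ``order="frame-first"`` extremizes each frame
    and averages the extrema.
    """
    if not profiles:
        raise ValueError("at least one frame is required")
    pg = np.stack([p.p_gamma for p in profiles])
    if order == "profile-first":
        mean = pg.mean(axis=0)
        p_h, p_l = float(mean.max()), float(mean.min())
    elif order == "frame-first":
        p_h = float(pg.max(axis=1).mean())
        p_l = float(pg.min(axis=1).mean())
    else:
        raise ValueError(f"unknown averaging order {order!r}")
    return PhasePoint(p_h=p_h, p_l=p_l, temperature=temperature, salt=salt,
                      averaging_order=order)


def mean_profile(profiles: Sequence[DensityProfile]) -> np.ndarray:
    return np.stack([p.p_gamma for p in profiles]).mean(axis=0)


# ---------------------------------------------------------------------------
# critical temperature


@dataclass
class TcrEstimate:
    t_cr: Optional[float]
    status: str  # "crossing" | "no-llps" | "lower-bound"


def tcr_threshold(
    series: Sequence[tuple[float, float]], threshold: float = LLPS_ABSENT
) -> TcrEstimate:
    """Critical temperature from the threshold crossing of P_H - P_L vs T.

    Linear interpolation to the crossing between the bracketing pair. A
    series never above threshold yields ``no-llps``; never below yields a
    lower bound at the maximum simulated temperature. For non-monotone
    series the highest-temperature crossing is used (with a warning).
    """
    pts = sorted(series)
    if len(pts) < 2:
        raise ValueError("need at least two temperatures")
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.all(v < threshold):
        return TcrEstimate(t_cr=None, status="no-llps")
    if np.all(v > threshold):
        warnings.warn("P_H - P_L never drops below threshold; reporting a lower bound")
        return TcrEstimate(t_cr=float(t[-1]), status="lower-bound")
    crossings = []
    for k in range(len(pts) - 1):
        hi, lo = v[k], v[k + 1]
        if hi >= threshold >= lo and hi != lo:
            crossings.append(
                float(t[k] + (hi - threshold) / (hi - lo) * (t[k + 1] - t[k]))
            )
    if not crossings:  # plateau exactly at threshold
        crossings.append(float(t[np.argmin(np.abs(v - threshold))]))
    if len(crossings) > 1:
        warnings.warn("non-monotone order-parameter series; using the highest crossing")
    return TcrEstimate(t_cr=max(crossings), status="crossing")


@dataclass
class CriticalFit:
    amplitude: Optional[float]
    t_cr: Optional[float]
    beta: Optional[float]
    threshold_t_cr: TcrEstimate = None
    converged: bool = False


def fit_critical(
    series: Sequence[tuple[float, float]], threshold: float = LLPS_ABSENT
) -> CriticalFit:
    """Fit order parameter = A (T_cr - T)^beta by nonlinear least squares.

    Only points with a positive order parameter enter the fit; fewer than
    four such points yields a threshold-only result. Initialization:
    T_cr0 = max fitted T + 0.5, beta0 = 0.325, A0 from the largest point.
    """
    thr = tcr_threshold(series, threshold) if len(series) >= 2 else None
    pts = sorted((t, v) for t, v in series if v > 0)
    if len(pts) < 4:
        return CriticalFit(None, None, None, threshold_t_cr=thr, converged=False)
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    tcr0 = float(t.max()) + 0.5
    beta0 = 0.325
    k = int(np.argmax(y))
    a0 = float(y[k] / (tcr0 - t[k]) ** beta0)

    def model(temp, a, tcr, beta):
        gap = np.clip(tcr - temp, 1e-12, None)
        return a * gap**beta

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[a0, tcr0, beta0],
            bounds=([0.0, float(t.max()), 1e-3], [np.inf, np.inf, 5.0]),
            maxfev=20_000,
        )
    except RuntimeError:
        return CriticalFit(None, None, None, threshold_t_cr=thr, converged=False)
    return CriticalFit(
        amplitude=float(popt[0]),
        t_cr=float(popt[1]),
        beta=float(popt[2]),
        threshold_t_cr=thr,
        converged=True,
    )


# ---------------------------------------------------------------------------
# per-chain geometry


def head_end_distance(config: Configuration, topology: Topology) -> np.ndarray:
    """Per-chain first-to-last bead Euclidean distance, in Angstrom."""
    unwrapped = config.unwrap_chains(topology)
    L = topology.chain_length
    a_bond = 0.38
    d = np.empty(topology.n_chains)
    for c in range(topology.n_chains):
        s = c * L
        seg = unwrapped[s : s + L]
        if L > 1:
            blen = np.linalg.norm(np.diff(seg, axis=0), axis=1)
            if np.any(blen > 2.0 * a_bond):
                raise ValueError(f"broken chain unwrapping on chain {c}")
        d[c] = np.linalg.norm(seg[-1] - seg[0])
    return d * 10.0  # nm -> Angstrom


def chain_centers(config: Configuration, topology: Topology) -> np.ndarray:
    """Per-chain centers of mass (uniform bead mass), computed on unwrapped
    chains, then wrapped into the box."""
    unwrapped = config.unwrap_chains(topology)
    L = topology.chain_length
    cm = unwrapped.reshape(topology.n_chains, L, 3).mean(axis=1)
    return cm - config.box * np.floor(cm / config.box)


@dataclass
class SlabCenter:
    z0: float
    degenerate: bool


def slab_center(config: Configuration, resultant_tol: float = 0.05) -> SlabCenter:
    """Periodic (circular-mean) center of the bead mass along z.

    When the circular mean is degenerate (near-uniform mass, resultant
    length below *resultant_tol*) the center of the maximum-density
    window is used instead and the result is flagged.
    """
    z = config.wrapped()[:, 2]
    box_z = float(config.box[2])
    theta = 2.0 * np.pi * z / box_z
    vec = np.mean(np.exp(1j * theta))
    if np.abs(vec) < resultant_tol:
        prof = density_profile(config)
        k = int(np.argmax(prof.m_gamma))
        return SlabCenter(z0=(k + 0.5) * prof.window_length, degenerate=True)
    z0 = (box_z / (2.0 * np.pi)) * float(np.angle(vec))
    return SlabCenter(z0=z0 % box_z, degenerate=False)


def chain_displacement(
    config: Configuration, topology: Topology, z0: float
) -> np.ndarray:
    """|z| per chain: minimum over periodic mirrors of |z_CM - z0|, nm."""
    cm_z = chain_centers(config, topology)[:, 2]
    box_z = float(config.box[2])
    dz = cm_z - z0
    dz -= box_z * np.round(dz / box_z)
    return np.abs(dz)


# ---------------------------------------------------------------------------
# windowed statistics along the |z| reaction coordinate


@dataclass
class WindowedStats:
    edges: np.ndarray            # nm, length n_windows + 1
    fraction: np.ndarray         # chains in window / total chain-frames
    count: np.ndarray
    mean: np.ndarray             # nan where empty
    sem: np.ndarray              # standard error; nan where undefined
    excluded: np.ndarray         # bool, windows beyond the boundary cut

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def windowed_stats(
    values: np.ndarray,
    z_disp: np.ndarray,
    box_z: float,
    n_windows: int = 30,
    z_max_excluded: float = 140.0,
) -> WindowedStats:
    """Per-|z|-window chain fraction and value mean/standard error.

    *values* and *z_disp* (nm) are paired, pooled over frames (any
    matching shape). The standard error is the standard deviation across
    contributing chain-frame values divided by sqrt(count). Windows whose
    lower edge lies at or beyond *z_max_excluded* nm are still reported
    but flagged excluded (boundary effects).
    """
    values = np.asarray(values, dtype=float).ravel()
    z = np.asarray(z_disp, dtype=float).ravel()
    if values.shape != z.shape:
        raise ValueError("values and z_disp must be paired")
    zmax = box_z / 2.0
    edges = np.linspace(0.0, zmax, n_windows + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_windows - 1)
    count = np.bincount(idx, minlength=n_windows)
    mean = np.full(n_windows, np.nan)
    sem = np.full(n_windows, np.nan)
    for w in range(n_windows):
        sel = values[idx == w]
        if sel.size:
            mean[w] = sel.mean()
            if sel.size > 1:
                sem[w] = sel.std(ddof=1) / np.sqrt(sel.size)
            else:
                sem[w] = 0.0
    return WindowedStats(
        edges=edges,
        fraction=count / z.size,
        count=count,
        mean=mean,
        sem=sem,
        excluded=edges[:-1] >= z_max_excluded,
    )


# ---------------------------------------------------------------------------
# electrostatic contacts


def electrostatic_contacts(
    config: Configuration,
    topology: Topology,
    params: ModelParams,
    cutoff: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Opposite-charge bead pairs closer than *cutoff* (minimum image).

    Returns per-chain (E_intra, E_inter); an inter-chain attraction is
    credited once to each of the two chains. Refuses to run in screened
    mode, where the counts would be meaningless.
    """
    if params.screened:
        raise ValueError(
            "electrostatic contacts are only defined with explicit charges; "
            "the salt mode is 'screened'"
        )
    wrapped = config.wrapped()
    wrapped = np.minimum(wrapped, np.nextafter(config.box, -np.inf))
    tree = cKDTree(wrapped, boxsize=config.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    e_intra = np.zeros(topology.n_chains, dtype=np.int64)
    e_inter = np.zeros(topology.n_chains, dtype=np.int64)
    if pairs.size == 0:
        return e_intra, e_inter
    q = topology.charges
    chain = topology.chain_of_bead
    # strictly-below-cutoff, opposite charges only
    d = minimum_image(
        config.positions[pairs[:, 1]] - config.positions[pairs[:, 0]], config.box
    )
    r = np.linalg.norm(d, axis=1)
    keep = (r < cutoff) & (q[pairs[:, 0]] * q[pairs[:, 1]] == -1)
    for i, j in pairs[keep]:
        ci, cj = chain[i], chain[j]
        if ci == cj:
            e_intra[ci] += 1
        else:
            e_inter[ci] += 1
            e_inter[cj] += 1
    return e_intra, e_inter


# ---------------------------------------------------------------------------
# chain-pair radial distribution functions


@dataclass
class ChainPairRdf:
    r: np.ndarray                  # bin centers, nm
    g: np.ndarray                  # (n_partners, n_bins)
    partners: np.ndarray           # partner chain indices
    peak1: np.ndarray              # nm; nan where the histogram is empty


def chain_pair_rdf(
    frames: Sequence[Configuration],
    topology: Topology,
    reference_chain: int = 0,
    bin_width: float = 0.1,
    smooth: int = 3,
) -> ChainPairRdf:
    """Bead-bead g(r) between the reference chain and every other chain.

    Normalized by the ideal-gas expectation in the periodic box; peak1 is
    the bin center of the global maximum of each (moving-average
    smoothed) curve. n-1 peak1 values for n chains.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    box = frames[0].box
    r_max = 0.5 * float(np.min(box))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    if edges[-1] > r_max:
        edges = edges[edges <= r_max + 1e-12]
    n_bins = len(edges) - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    L = topology.chain_length
    ref = topology.bead_range(reference_chain)
    partners = np.array(
        [c for c in range(topology.n_chains) if c != reference_chain]
    )
    hist = np.zeros((len(partners), n_bins))
    for config in frames:
        pos = config.positions
        rpos = pos[ref]
        for k, c in enumerate(partners):
            ppos = pos[topology.bead_range(c)]
            d = minimum_image(
                ppos[None, :, :] - rpos[:, None, :], box
            ).reshape(-1, 3)
            r = np.linalg.norm(d, axis=1)
            h, _ = np.histogram(r, bins=edges)
            hist[k] += h
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    volume = float(np.prod(box))
    expected = L * L * len(frames) * shell / volume
    g = hist / expected
    peak1 = np.full(len(partners), np.nan)
    kern = np.ones(smooth) / smooth
    for k in range(len(partners)):
        if hist[k].sum() == 0:
            continue
        gs = np.convolve(g[k], kern, mode="same") if smooth > 1 else g[k]
        peak1[k] = centers[int(np.argmax(gs))]
    return ChainPairRdf(r=centers, g=g, partners=partners, peak1=peak1)


# ---------------------------------------------------------------------------
# P / D / F form classification


@dataclass
class FormClassification:
    window_labels: list            # per z-window label in {"P", "D", "F"}
    chain_labels: Optional[np.ndarray] = None
    sigma_by_label: dict = field(default_factory=dict)


def classify_forms(
    mean_p_gamma: np.ndarray,
    box_z: float,
    chain_z: Optional[np.ndarray] = None,
    chain_values: Optional[np.ndarray] = None,
) -> FormClassification:
    """Label density windows packed (P), dispersed (D) or fully-spread (F).

    With LLPS absent (P_H - P_L < 0.07) every window is F. Otherwise the
    condensed region is the contiguous (periodically wrapped) window set
    around the density maximum whose time-averaged P_gamma exceeds the
    mid-density (P_H + P_L)/2; those windows are P and the rest D.

    If per-chain wrapped z coordinates (and optionally paired values,
    e.g. head-end distances) are given, chains are labeled by their
    window and the pooled standard deviation of the values per label is
    reported for phase-diagram scatter plots.
    """
    p = np.asarray(mean_p_gamma, dtype=float)
    nw = len(p)
    p_h, p_l = float(p.max()), float(p.min())
    if p_h - p_l < LLPS_ABSENT:
        labels = ["F"] * nw
    else:
        mid = 0.5 * (p_h + p_l)
        labels = ["D"] * nw
        kmax = int(np.argmax(p))
        labels[kmax] = "P"
        k = kmax
        while True:  # grow right (wrapping)
            k2 = (k + 1) % nw
            if k2 == kmax or p[k2] <= mid:
                break
            labels[k2] = "P"
            k = k2
        k = kmax
        while True:  # grow left (wrapping)
            k2 = (k - 1) % nw
            if k2 == kmax or p[k2] <= mid or labels[k2] == "P":
                break
            labels[k2] = "P"
            k = k2
    out = FormClassification(window_labels=labels)
    if chain_z is not None:
        chain_z = np.asarray(chain_z, dtype=float).ravel()
        wl = box_z / nw
        idx = np.clip((chain_z // wl).astype(int), 0, nw - 1)
        out.chain_labels = np.array([labels[i] for i in idx])
        if chain_values is not None:
            vals = np.asarray(chain_values, dtype=float).ravel()
            for lab in ("P", "D", "F"):
                sel = vals[out.chain_labels == lab]
                if sel.size > 1:
                    out.sigma_by_label[lab] = float(sel.std(ddof=1))
    return out
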