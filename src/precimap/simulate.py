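"""Synthetic cohorts of grayordinate time series with planted network topology.

Real extended-acquisition neonatal datasets are not publicly available, so
this module simulates them: a shared group parcellation on a toy surface,
per-subject boundary perturbations (individual-specific topology), BOLD-like
low-frequency signals with network-structured covariance (including the
anticorrelations characteristic of the infant regime), and framewise-
displacement traces for motion censoring.

Signal model
------------
Each network k has a latent time course; latents are low-pass filtered
Gaussian series (cutoff 0.1 Hz) with population correlation given by a K x K
coupling matrix.  A grayordinate in network k observes

    sqrt(w) * latent_k  +  sqrt(1 - w) * noise_g

with independent (also low-passed) noise and w the within-network signal
fraction, the SNR dial.  Under w = 1 all same-network grayordinates share one
time course and cross-network sample correlations converge to the coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .labels import LabelMap, LabelTable, UNASSIGNED
from .surface import SurfaceMesh, build_toy_surface
from .timeseries import GrayordinateSeries


# --------------------------------------------------------------------------
# network coupling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkCoupling:
    """Target correlation matrix between network latent time courses."""

    coupling: np.ndarray  # (K, K), symmetric, unit diagonal

    def __post_init__(self) -> None:
        c = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "coupling", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("coupling must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("coupling must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("coupling must have unit diagonal")

    @property
    def k(self) -> int:
        return self.coupling.shape[0]

    def repaired(self, tol: float = 1e-10) -> "NetworkCoupling":
        """Project onto the PSD cone by eigenvalue clipping, re-normalize diag."""
        vals, vecs = np.linalg.eigh(self.coupling)
        if vals.min() >= -tol:
            return self
        c = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.diag(c))
        if np.any(d <= 0):
            raise ValueError("coupling is not repairable to a correlation matrix")
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        return NetworkCoupling((c + c.T) / 2)

    def factor(self) -> np.ndarray:
        """A matrix L with L @ L.T equal to the (repaired) coupling."""
        c = self.repaired().coupling
        vals, vecs = np.linalg.eigh(c)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))

    @classmethod
    def identity(cls, k: int) -> "NetworkCoupling":
        return cls(np.eye(k))


def infant_coupling(table: LabelTable, anticorrelation: float = -0.3) -> NetworkCoupling:
    """Default "infant" coupling: the dorsal sensorimotor network anticorrelated
    with the default-mode, dorsal-attention, and frontoparietal networks.

    Networks absent from the table are simply skipped, so the preset degrades
    gracefully at small K.
    """
    k = len(table)
    c = np.eye(k)
    names = list(table.names)
    if "SMd" in names:
        i = names.index("SMd")
        for other in ("DMN", "DAN", "FP"):
            if other in names:
                j = names.index(other)
                c[i, j] = c[j, i] = anticorrelation
    return NetworkCoupling(c).repaired()


# --------------------------------------------------------------------------
# configuration and cohort containers
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-condition knobs for a synthetic cohort.

    Defaults emulate the extended-acquisition neonatal regime: TR 0.8 s,
    per-subject durations drawn uniformly from 20-44.7 minutes, moderate
    within-network signal (w = 0.8), 20% boundary jitter, and an FD trace
    whose spikes censor roughly 10% of frames at the 0.3 mm threshold.
    """

    n_subjects: int = 10
    n_grayordinates: int = 2000
    n_networks: int = 14
    tr: float = 0.8
    duration_minutes: tuple[float, float] = (20.0, 44.7)  # uniform range; or scalar
    boundary_jitter: float = 0.2
    within_network_signal_fraction: float = 0.8
    coupling: NetworkCoupling | None = None   # None -> infant preset
    fd_mean: float = 0.1
    fd_sd: float = 0.05
    fd_spike_prob: float = 0.1
    fd_spike_scale: float = 0.3
    lowpass_hz: float = 0.1
    geometry: str = "grid"
    spacing_mm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        for name in ("boundary_jitter", "within_network_signal_fraction",
                     "fd_spike_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_jitter > 0.5:
            raise ValueError("boundary_jitter above 0.5 is not supported")
        if self.n_networks > 14:
            raise ValueError("at most 14 networks are supported by the label table")

    @property
    def table(self) -> LabelTable:
        return LabelTable.default(self.n_networks)

    def duration_for(self, rng: np.random.Generator) -> float:
        d = self.duration_minutes
        if np.isscalar(d):
            return float(d)
        lo, hi = d
        return float(rng.uniform(lo, hi))


@dataclass
class SyntheticSubject:
    """One simulated subject: planted topology, series, and FD trace."""

    subject_id: str
    truth: LabelMap
    series: GrayordinateSeries
    fd: np.ndarray

    def __post_init__(self) -> None:
        if self.fd.shape != (self.series.n_frames,):
            raise ValueError("fd length must equal series frame count")


@dataclass
class Cohort:
    """A simulated multi-subject study sharing one mesh and group truth."""

    mesh: SurfaceMesh
    group_truth: LabelMap
    subjects: list[SyntheticSubject]
    config: SimulationConfig

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


# --------------------------------------------------------------------------
# planting the parcellation
# --------------------------------------------------------------------------

def plant_group_parcellation(mesh: SurfaceMesh, k: int, seed: int = 0) -> LabelMap:
    """Partition the mesh into K spatially contiguous networks.

    Seeds are chosen by farthest-point sampling on geodesic distance, then
    regions grow by round-robin breadth-first search, which yields contiguous,
    approximately balanced networks deterministically for a given seed.
    """
    n = mesh.node_count
    if k < 2:
        raise ValueError("need at least 2 networks")
    if k > n / 8:
        raise ValueError(
            f"K={k} too large for {n} grayordinates: networks would be too small"
        )
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    seeds = [first]
    dist_to_seeds = mesh.geodesic_distances(sources=first)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist_to_seeds))  # ties -> lowest index
        seeds.append(nxt)
        dist_to_seeds = np.minimum(dist_to_seeds, mesh.geodesic_distances(sources=nxt))

    labels = np.zeros(n, dtype=np.int64)
    frontiers: list[list[int]] = []
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        frontiers.append([s])
    remaining = n - k
    adj = mesh.adjacency
    while remaining > 0:
        progressed = False
        for lab in range(1, k + 1):
            frontier = frontiers[lab - 1]
            claimed = None
            while frontier:
                node = frontier[0]
                nbrs = adj.indices[adj.indptr[node] : adj.indptr[node + 1]]
                free = nbrs[labels[nbrs] == 0]
                if free.size == 0:
                    frontier.pop(0)
                    continue
                claimed = int(free[0])
                break
            if claimed is not None:
                labels[claimed] = lab
                frontier.append(claimed)
                remaining -= 1
                progressed = True
            if remaining == 0:
                break
        if not progressed:  # pragma: no cover - connected mesh always progresses
            raise RuntimeError("region growing stalled on a disconnected mesh")

    table = LabelTable.default(k)
    sizes = np.bincount(labels, minlength=k + 1)[1:]
    min_size = math.ceil(n / (4 * k))
    if sizes.min() < min_size:  # pragma: no cover - balanced growth prevents this
        raise RuntimeError(
            f"planted network of size {sizes.min()} below minimum {min_size}"
        )
    return LabelMap(labels, table)


def perturb_topology(
    group: LabelMap, mesh: SurfaceMesh, boundary_jitter: float, seed: int = 0
) -> LabelMap:
    """Individualize a parcellation by flipping boundary grayordinates.

    Each grayordinate adjacent to a network boundary changes, with probability
    ``boundary_jitter``, to the label of a uniformly chosen differently-labeled
    neighbor.  Flips are evaluated against the unperturbed map, so interior
    grayordinates never change and no foreign-label islands are created.
    """
    if not 0.0 <= boundary_jitter <= 0.5:
        raise ValueError("boundary_jitter must be in [0, 0.5]")
    labels = group.labels
    out = labels.copy()
    if boundary_jitter == 0:
        return LabelMap(out, group.table)
    rng = np.random.default_rng(seed)
    adj = mesh.adjacency
    for node in range(mesh.node_count):
        nbrs = adj.indices[adj.indptr[node] : adj.indptr[node + 1]]
        foreign = nbrs[labels[nbrs] != labels[node]]
        if foreign.size == 0:
            continue
        if rng.random() < boundary_jitter:
            out[node] = labels[int(rng.choice(foreign))]
    return LabelMap(out, group.table)


def boundary_mask(labels: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Grayordinates with at least one differently-labeled mesh neighbor."""
    adj = mesh.adjacency
    mask = np.zeros(labels.size, dtype=bool)
    for node in range(labels.size):
        nbrs = adj.indices[adj.indptr[node] : adj.indptr[node + 1]]
        if np.any(labels[nbrs] != labels[node]):
            mask[node] = True
    return mask


# --------------------------------------------------------------------------
# signal and motion simulation
# --------------------------------------------------------------------------

def _lowpass_gaussian(rng: np.random.Generator, shape: tuple[int, int],
                      cutoff_hz: float, tr: float) -> np.ndarray:
    """Columns of iid Gaussian noise, low-pass filtered and re-standardized."""
    x = rng.standard_normal(shape)
    n = shape[0]
    nyquist = 0.5 / tr
    if cutoff_hz <= 0 or cutoff_hz >= nyquist or n < 18:
        # unfiltered fallback for degenerate cutoffs or too-short series
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=0)) / sd
    b, a = sps.butter(2, cutoff_hz / nyquist)
    padlen = min(3 * (max(len(a), len(b)) - 1), n - 1)
    y = sps.filtfilt(b, a, x, axis=0, padlen=padlen)
    sd = y.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (y - y.mean(axis=0)) / sd


def simulate_bold(
    truth: LabelMap,
    coupling: NetworkCoupling,
    cfg: SimulationConfig,
    seed: int = 0,
    duration_minutes: float | None = None,
) -> GrayordinateSeries:
    """Simulate a grayordinate series from a planted topology.

    See the module docstring for the signal model.  Frame count is
    round(duration * 60 / TR).
    """
    if np.any(truth.labels == UNASSIGNED):
        raise ValueError("truth parcellation must assign every grayordinate")
    k = len(truth.table)
    if coupling.k != k:
        raise ValueError("coupling size must match network count")
    dur = duration_minutes
    if dur is None:
        d = cfg.duration_minutes
        dur = float(d) if np.isscalar(d) else float(d[0])
    n_frames = int(round(dur * 60.0 / cfg.tr))
    rng = np.random.default_rng(seed)
    latents = _lowpass_gaussian(rng, (n_frames, k), cfg.lowpass_hz, cfg.tr)
    latents = latents @ coupling.factor().T
    g = truth.n_grayordinates
    noise = _lowpass_gaussian(rng, (n_frames, g), cfg.lowpass_hz, cfg.tr)
    w = cfg.within_network_signal_fraction
    data = math.sqrt(w) * latents[:, truth.labels - 1] + math.sqrt(1.0 - w) * noise
    return GrayordinateSeries(data, cfg.tr)


def simulate_fd(n_frames: int, cfg: SimulationConfig, seed: int = 0) -> np.ndarray:
    """Framewise displacement trace: lognormal baseline plus Bernoulli spikes.

    The baseline is moment-matched to (fd_mean, fd_sd); spike frames are
    replaced by ``fd_spike_scale + Exponential(fd_spike_scale)`` so that the
    exceedance fraction at the 0.3 mm threshold tracks ``fd_spike_prob``.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    m, s = cfg.fd_mean, cfg.fd_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    fd = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_frames)
    spikes = rng.random(n_frames) < cfg.fd_spike_prob
    fd[spikes] = cfg.fd_spike_scale + rng.exponential(
        cfg.fd_spike_scale, size=int(spikes.sum())
    )
    return fd


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate a full cohort; a pure function of the configuration."""
    root = np.random.SeedSequence(cfg.rng_seed)
    mesh_seed, *subject_seeds = root.spawn(cfg.n_subjects + 1)
    mesh = build_toy_surface(cfg.n_grayordinates, cfg.geometry, cfg.spacing_mm)
    parc_rng_seed = mesh_seed.generate_state(1)[0] % (2**31)
    group = plant_group_parcellation(mesh, cfg.n_networks, seed=int(parc_rng_seed))
    coupling = cfg.coupling if cfg.coupling is not None else infant_coupling(cfg.table)
    subjects = []
    for s_idx, ss in enumerate(subject_seeds):
        topo_seed, bold_seed, fd_seed, dur_seed = (
            int(x % (2**31)) for x in ss.generate_state(4)
        )
        dur = cfg.duration_for(np.random.default_rng(dur_seed))
        truth = perturb_topology(group, mesh, cfg.boundary_jitter, seed=topo_seed)
        series = simulate_bold(truth, coupling, cfg, seed=bold_seed,
                               duration_minutes=dur)
        fd = simulate_fd(series.n_frames, cfg, seed=fd_seed)
        subjects.append(
            SyntheticSubject(f"sub-{s_idx + 1:03d}", truth, series, fd)
        )
    return Cohort(mesh, group, subjects, replace(cfg))
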