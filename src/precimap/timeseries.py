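"""Frame censoring, surface smoothing, split halves, and frame sampling.

All operations act on :class:`GrayordinateSeries`, a frames x grayordinates
matrix carrying its repetition time (TR) and a per-frame retention mask.
Censoring masks frames rather than deleting them, so temporal structure is
preserved for the split-half and sampling operations downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .surface import SurfaceMesh, gaussian_smoothing_weights


@dataclass
class GrayordinateSeries:
    """BOLD-like signal matrix (frames x grayordinates) with TR and mask."""

    data: np.ndarray               # (F, G) float, arbitrary BOLD units
    tr: float                      # seconds per frame
    retained: np.ndarray = field(default=None)  # (F,) bool; default all True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x grayordinates)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.retained is None:
            self.retained = np.ones(self.data.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.data.shape[0],):
            raise ValueError("retention mask length must equal frame count")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_grayordinates(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_minutes(self) -> float:
        return self.n_retained * self.tr / 60.0

    @property
    def retained_data(self) -> np.ndarray:
        """The (n_retained, G) submatrix of retained frames."""
        return self.data[self.retained]

    def copy(self) -> "GrayordinateSeries":
        return GrayordinateSeries(self.data.copy(), self.tr, self.retained.copy())


def censor_frames(
    series: GrayordinateSeries, fd: np.ndarray, threshold: float = 0.3
) -> GrayordinateSeries:
    """Drop high-motion frames: retain frame t iff fd[t] < threshold (mm).

    Frames already censored stay censored; data values are untouched.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (series.n_frames,):
        raise ValueError(
            f"fd has {fd.size} values but series has {series.n_frames} frames"
        )
    if threshold <= 0:
        raise ValueError("FD threshold must be positive")
    return GrayordinateSeries(series.data, series.tr, series.retained & (fd < threshold))


def smooth_series(
    series: GrayordinateSeries,
    mesh: SurfaceMesh,
    sigma_mm: float,
    weights=None,
) -> GrayordinateSeries:
    """Within-frame geodesic Gaussian smoothing on the surface mesh.

    Each grayordinate's value becomes a Gaussian-weighted mean of grayordinates
    within 3·sigma geodesic distance (weights normalized to sum 1).  Pass a
    precomputed ``weights`` matrix (from :func:`gaussian_smoothing_weights`)
    to amortize the geodesic computation across many series on one mesh.
    """
    if mesh.node_count != series.n_grayordinates:
        raise ValueError("mesh node count must equal grayordinate count")
    if sigma_mm == 0:
        return series.copy()
    if weights is None:
        weights = gaussian_smoothing_weights(mesh, sigma_mm)
    smoothed = series.data @ weights.T
    return GrayordinateSeries(np.asarray(smoothed), series.tr, series.retained.copy())


def split_halves(
    series: GrayordinateSeries,
) -> tuple[GrayordinateSeries, GrayordinateSeries]:
    """Split the full frame index range at its midpoint, preserving order.

    An odd frame goes to the first half.  Because censored frames need not be
    balanced across the midpoint, the two halves' retained minutes may differ.
    """
    if series.n_retained < 2:
        raise ValueError("need at least 2 retained frames to split")
    mid = math.ceil(series.n_frames / 2)
    first = GrayordinateSeries(series.data[:mid], series.tr, series.retained[:mid])
    second = GrayordinateSeries(series.data[mid:], series.tr, series.retained[mid:])
    return first, second


def sample_frames(
    series: GrayordinateSeries,
    minutes: float,
    mode: str = "continuous",
    seed: int = 0,
) -> GrayordinateSeries:
    """Select round(minutes·60/TR) retained frames, continuously or at random.

    ``continuous`` takes a run of consecutive retained frames starting at a
    seed-chosen valid start; ``random`` draws uniformly without replacement.
    The result keeps the full data matrix and marks only the selection as
    retained (a subset of the input's retained frames).
    """
    if mode not in ("continuous", "random"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    n_wanted = int(round(minutes * 60.0 / series.tr))
    if n_wanted < 1:
        raise ValueError("requested sample is shorter than one frame")
    retained_idx = np.flatnonzero(series.retained)
    if n_wanted > retained_idx.size:
        short = (n_wanted - retained_idx.size) * series.tr / 60.0
        raise ValueError(
            f"requested {minutes:g} min ({n_wanted} frames) but only "
            f"{series.retained_minutes:g} min retained (short by {short:.2f} min)"
        )
    rng = np.random.default_rng(seed)
    if mode == "continuous":
        start = rng.integers(0, retained_idx.size - n_wanted + 1)
        chosen = retained_idx[start : start + n_wanted]
    else:
        chosen = rng.choice(retained_idx, size=n_wanted, replace=False)
    mask = np.zeros(series.n_frames, dtype=bool)
    mask[chosen] = True
    return GrayordinateSeries(series.data, series.tr, mask)
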