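"""Dense connectivity matrices and seed-based correlation maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import GrayordinateSeries


@dataclass
class ConnectivityMatrix:
    """All-pairs Pearson correlation of grayordinate time series."""

    values: np.ndarray     # (G, G), symmetric, unit diagonal, in [-1, 1]
    source_frames: int     # retained frames that produced it

    @property
    def n_grayordinates(self) -> int:
        return int(self.values.shape[0])


@dataclass
class SeedMap:
    """Correlation of every grayordinate with one network's mean time series."""

    values: np.ndarray       # (G,) in [-1, 1]
    network_id: int | None = None


def _check_variance(x: np.ndarray) -> None:
    dead = np.flatnonzero(np.ptp(x, axis=0) == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance grayordinate(s) over retained frames: {dead[:10].tolist()}"
        )


def dense_connectivity(series: GrayordinateSeries) -> ConnectivityMatrix:
    """Correlate every grayordinate's retained time series against all others."""
    x = series.retained_data
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 retained frames, have {x.shape[0]}")
    _check_variance(x)
    c = np.corrcoef(x, rowvar=False)
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix((c + c.T) / 2.0, source_frames=x.shape[0])


def seed_map(series: GrayordinateSeries, roi) -> SeedMap:
    """Correlate the unweighted ROI-mean ("seed") series with every grayordinate.

    The seed is the mean of the raw retained series across the ROI's
    grayordinates (not standardized first).
    """
    roi = np.asarray(sorted(roi), dtype=int)
    if roi.size == 0:
        raise ValueError("ROI must be non-empty")
    x = series.retained_data
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 retained frames, have {x.shape[0]}")
    seed = x[:, roi].mean(axis=1)
    if seed.std() == 0:
        raise ValueError("seed series has zero variance")
    _check_variance(x)
    seed_c = seed - seed.mean()
    xc = x - x.mean(axis=0)
    num = xc.T @ seed_c
    den = np.sqrt((xc**2).sum(axis=0) * (seed_c**2).sum())
    vals = num / den
    np.clip(vals, -1.0, 1.0, out=vals)
    return SeedMap(vals)
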