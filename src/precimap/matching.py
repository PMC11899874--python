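"""Template matching: assign each grayordinate to the network template its
whole-brain connectivity profile most resembles, via the eta-squared index.

For two profiles a, b of length G, with per-position means m_i = (a_i+b_i)/2
and grand mean Mbar over all 2G values,

    eta2 = 1 - sum_i [(a_i - m_i)^2 + (b_i - m_i)^2]
               / sum_i [(a_i - Mbar)^2 + (b_i - Mbar)^2]

eta2 is 1 for identical profiles and lies in [0, 1] because the per-pair mean
minimizes within-pair squared deviation.  Similarity is computed against the
thresholded template over ALL grayordinate positions (zeros outside template
support included), and each grayordinate takes the argmax network
(winner-take-all; exact ties broken by lowest label id and logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, dense_connectivity
from .labels import LabelMap
from .surface import SurfaceMesh, gaussian_smoothing_weights
from .templates import TemplateSet
from .timeseries import GrayordinateSeries, censor_frames, smooth_series

logger = logging.getLogger(__name__)


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Similarity of two equal-length profiles (1 identical, 0 discordant).

    Symmetric in its arguments; not invariant to rescaling one argument alone.
    If both vectors are constant and equal the ratio is 0/0; this degenerate
    case is defined as 1.0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1-D vectors of length >= 2")
    ss_within = 0.5 * np.sum((a - b) ** 2)
    grand = 0.5 * (a.mean() + b.mean())
    ss_total = np.sum((a - grand) ** 2) + np.sum((b - grand) ** 2)
    if ss_total <= 0:
        warnings.warn("eta_squared of two identical constant vectors; defining as 1.0")
        return 1.0
    return float(np.clip(1.0 - ss_within / ss_total, 0.0, 1.0))


@dataclass
class EtaProfile:
    """Per-grayordinate eta-squared similarity to every template network."""

    values: np.ndarray   # (G, K) in [0, 1]
    winner: np.ndarray   # (G,) label ids (argmax; ties -> lowest label id)


def eta_profile_matrix(conn: ConnectivityMatrix, templates: TemplateSet) -> np.ndarray:
    """Vectorized eta-squared of every connectivity row against every template.

    Uses the algebraic identities SSwithin = ||a - b||^2 / 2 and
    SStotal = sum a^2 + sum b^2 - (sum a + sum b)^2 / (2G).
    """
    g = conn.n_grayordinates
    if templates.n_grayordinates != g:
        raise ValueError(
            f"connectivity has {g} grayordinates, templates {templates.n_grayordinates}"
        )
    a = conn.values                        # (G, G)
    t = templates.maps                     # (K, G)
    sa, qa = a.sum(axis=1), (a**2).sum(axis=1)
    st, qt = t.sum(axis=1), (t**2).sum(axis=1)
    # ||a - t||^2 = |a|^2 + |t|^2 - 2 a.t
    cross = a @ t.T
    ss_within = 0.5 * (qa[:, None] + qt[None, :] - 2.0 * cross)
    ss_total = qa[:, None] + qt[None, :] - (sa[:, None] + st[None, :]) ** 2 / (2.0 * g)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 1.0 - ss_within / ss_total
    eta[~np.isfinite(eta)] = 1.0           # constant-equal degenerate pairs
    return np.clip(eta, 0.0, 1.0)


def match_templates(
    conn: ConnectivityMatrix, templates: TemplateSet
) -> tuple[LabelMap, EtaProfile]:
    """Winner-take-all network assignment from eta-squared similarities."""
    eta = eta_profile_matrix(conn, templates)
    best = np.argmax(eta, axis=1)          # first max -> lowest label id
    n_ties = int(
        ((eta == eta.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum()
    )
    if n_ties:
        logger.info("template matching: %d grayordinates had tied eta2 maxima "
                    "(broken by lowest label id)", n_ties)
    ids = np.asarray(templates.table.ids)
    labels = ids[best]
    return LabelMap(labels, templates.table), EtaProfile(eta, labels)


class TemplateMatchingMapper:
    """The full single-subject mapping procedure as a reusable callable.

    smooth (geodesic Gaussian, default sigma 2.25 mm) -> censor (FD < 0.3 mm)
    -> dense connectivity -> eta-squared winner-take-all assignment.
    Smoothing weights are precomputed once per mesh.
    """

    def __init__(
        self,
        templates: TemplateSet,
        mesh: SurfaceMesh,
        sigma_mm: float = 2.25,
        fd_threshold: float = 0.3,
    ) -> None:
        self.templates = templates
        self.mesh = mesh
        self.sigma_mm = sigma_mm
        self.fd_threshold = fd_threshold
        self._weights = (
            gaussian_smoothing_weights(mesh, sigma_mm) if sigma_mm > 0 else None
        )

    def __call__(
        self, series: GrayordinateSeries, fd: np.ndarray | None = None
    ) -> LabelMap:
        if self.sigma_mm > 0:
            series = smooth_series(series, self.mesh, self.sigma_mm,
                                   weights=self._weights)
        if fd is not None:
            series = censor_frames(series, fd, self.fd_threshold)
        conn = dense_connectivity(series)
        labels, _ = match_templates(conn, self.templates)
        return labels
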