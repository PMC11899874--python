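"""Split-half reliability, inter-subject null distributions, data-amount
sampling curves, and the NMI-versus-minutes regression.

Similarity between two parcellations is normalized mutual information (NMI),
2·I(A;B) / (H(A) + H(B)), computed from the grayordinate contingency table.
NMI is label-permutation invariant and lies in [0, 1]; grayordinates
unassigned (0) in either map are excluded from the table by default (they
carry no claim, not a class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .labels import LabelMap, UNASSIGNED
from .timeseries import GrayordinateSeries, sample_frames, split_halves

logger = logging.getLogger(__name__)

Mapper = Callable[[GrayordinateSeries], LabelMap]


# --------------------------------------------------------------------------
# normalized mutual information
# --------------------------------------------------------------------------

def nmi(
    a: LabelMap | np.ndarray,
    b: LabelMap | np.ndarray,
    exclude_unassigned: bool = True,
    normalization: str = "arithmetic",
) -> float:
    """Normalized mutual information between two label maps.

    Normalizations: "arithmetic" (2I/(H1+H2), default), "max" (I/max),
    "sqrt" (I/sqrt(H1·H2)).  Both maps constant and identical -> 1.0;
    otherwise a zero entropy on either side -> 0.0.
    """
    la = a.labels if isinstance(a, LabelMap) else np.asarray(a)
    lb = b.labels if isinstance(b, LabelMap) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label maps must have equal length")
    if exclude_unassigned:
        keep = (la != UNASSIGNED) & (lb != UNASSIGNED)
        la, lb = la[keep], lb[keep]
    if la.size == 0:
        raise ValueError("no jointly assigned grayordinates")
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    table = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(table, (ia, ib), 1.0)
    pxy = table / table.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    h_a = float(-np.sum(px * np.log(px, where=px > 0, out=np.zeros_like(px))))
    h_b = float(-np.sum(py * np.log(py, where=py > 0, out=np.zeros_like(py))))
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])))
    if h_a == 0 and h_b == 0:
        return 1.0 if np.array_equal(np.unique(la), np.unique(lb)) else 0.0
    if h_a == 0 or h_b == 0:
        return 0.0
    if normalization == "arithmetic":
        denom = (h_a + h_b) / 2.0
    elif normalization == "max":
        denom = max(h_a, h_b)
    elif normalization == "sqrt":
        denom = float(np.sqrt(h_a * h_b))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(np.clip(mi / denom, 0.0, 1.0))


# --------------------------------------------------------------------------
# split-half reliability
# --------------------------------------------------------------------------

@dataclass
class ReliabilityRecord:
    """Within-subject split-half similarity and the halves' data amounts."""

    subject_id: str
    nmi_within: float
    minutes_half1: float
    minutes_half2: float
    method: str = "template_matching"

    @property
    def mean_minutes(self) -> float:
        return 0.5 * (self.minutes_half1 + self.minutes_half2)


def split_half_reliability(
    series: GrayordinateSeries,
    mapper: Mapper,
    subject_id: str = "",
    min_retained_minutes: float = 20.0,
    method: str = "template_matching",
) -> tuple[ReliabilityRecord | None, tuple[LabelMap, LabelMap] | None]:
    """Map each half of a (censored) series independently and compare by NMI.

    Subjects below the retained-minutes inclusion rule are skipped (returns
    (None, None) with a logged reason).  Also returns the two half maps so
    callers can build inter-subject null distributions without remapping.
    """
    if series.retained_minutes < min_retained_minutes:
        logger.info(
            "subject %s skipped: %.1f retained minutes < %.1f required",
            subject_id, series.retained_minutes, min_retained_minutes,
        )
        return None, None
    half1, half2 = split_halves(series)
    map1, map2 = mapper(half1), mapper(half2)
    rec = ReliabilityRecord(
        subject_id=subject_id,
        nmi_within=nmi(map1, map2),
        minutes_half1=half1.retained_minutes,
        minutes_half2=half2.retained_minutes,
        method=method,
    )
    return rec, (map1, map2)


@dataclass
class NullDistribution:
    """Inter-subject NMI null: all ordered cross-subject half pairs."""

    values: np.ndarray
    pairing: str = "cross"   # half-1 of i vs half-2 of j

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def se(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(self.values.size))

    @property
    def p5(self) -> float:
        return float(np.percentile(self.values, 5))

    @property
    def p95(self) -> float:
        return float(np.percentile(self.values, 95))


def inter_subject_null(
    half_maps: Sequence[tuple[LabelMap, LabelMap]], pairing: str = "cross"
) -> NullDistribution:
    """NMI over all ordered pairs of different subjects' halves.

    ``cross`` compares subject i's first half to subject j's second half
    (mirroring the within-subject construction); ``like`` compares first
    halves to first halves and second to second.
    """
    if len(half_maps) < 2:
        raise ValueError("need at least 2 subjects for an inter-subject null")
    vals = []
    for i, (a1, a2) in enumerate(half_maps):
        for j, (b1, b2) in enumerate(half_maps):
            if i == j:
                continue
            if pairing == "cross":
                vals.append(nmi(a1, b2))
            elif pairing == "like":
                vals.append(nmi(a1, b1) if i < j else nmi(a2, b2))
            else:
                raise ValueError(f"unknown pairing {pairing!r}")
    return NullDistribution(np.array(vals), pairing)


# --------------------------------------------------------------------------
# data-amount sampling curves
# --------------------------------------------------------------------------

DEFAULT_MINUTES_GRID: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0, 25.0)


@dataclass
class SamplingCurve:
    """Mean NMI versus sampled minutes for one subject and sampling mode."""

    subject_id: str
    minutes_grid: tuple[float, ...]
    mode: str
    repetitions: int
    mean_nmi: list[float | None]          # None where the grid point was infeasible
    all_nmi: list[list[float]]


def sampling_curve(
    half1: GrayordinateSeries,
    reference_map: LabelMap,
    mapper: Mapper,
    minutes_grid: Sequence[float] = DEFAULT_MINUTES_GRID,
    mode: str = "continuous",
    repetitions: int = 10,
    seed: int = 0,
    subject_id: str = "",
) -> SamplingCurve:
    """Map subsamples of the first half and compare each to the held-out map.

    Per grid point, ``repetitions`` subsamples are drawn (continuous mode
    randomizes the segment start; random mode redraws the frame set) and the
    NMI against the full-second-half reference map is averaged.  Grid points
    exceeding the available retained minutes are recorded as missing.
    """
    grid = tuple(minutes_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("minutes grid must be strictly increasing")
    means: list[float | None] = []
    all_vals: list[list[float]] = []
    for point_idx, minutes in enumerate(grid):
        needed = int(round(minutes * 60.0 / half1.tr))
        if needed > half1.n_retained:
            logger.info("subject %s: %g-minute point infeasible (%.1f min retained)",
                        subject_id, minutes, half1.retained_minutes)
            means.append(None)
            all_vals.append([])
            continue
        vals = []
        for rep in range(repetitions):
            rep_seed = int(
                np.random.SeedSequence([seed, point_idx, rep]).generate_state(1)[0]
                % (2**31)
            )
            sampled = sample_frames(half1, minutes, mode=mode, seed=rep_seed)
            vals.append(nmi(mapper(sampled), reference_map))
        means.append(float(np.mean(vals)))
        all_vals.append(vals)
    return SamplingCurve(subject_id, grid, mode, repetitions, means, all_vals)


# --------------------------------------------------------------------------
# NMI-versus-minutes regression
# --------------------------------------------------------------------------

def regress_nmi_on_minutes(records: Sequence[ReliabilityRecord]) -> dict[str, float]:
    """OLS of within-subject NMI on the subject's mean retained minutes per half.

    Returns slope, intercept, R^2, and the two-sided slope p-value.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to regress")
    x = np.array([r.mean_minutes for r in records])
    y = np.array([r.nmi_within for r in records])
    if x.std() == 0:
        raise ValueError("predictor (minutes) has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.pvalues[1]),
        "n": len(records),
    }
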