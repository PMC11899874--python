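"""Network template generation: per-subject seed maps, cross-subject
averaging, and the 1-SD support threshold.

A template set holds, for each network, the cohort-average seed-based
correlation map thresholded to keep only the grayordinates with the highest
connectivity; thresholded-out grayordinates are exactly zero, which encodes
the template's support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import seed_map
from .labels import LabelMap, LabelTable
from .timeseries import GrayordinateSeries


@dataclass
class TemplateSet:
    """Per-network averaged seed maps with thresholded support."""

    maps: np.ndarray            # (K, G); zero outside support
    table: LabelTable
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != len(self.table):
            raise ValueError("template row count must match label table size")
        if not self.support.any(axis=1).all():
            raise ValueError("every network template needs non-empty support")

    @property
    def support(self) -> np.ndarray:
        return self.maps != 0

    @property
    def n_networks(self) -> int:
        return int(self.maps.shape[0])

    @property
    def n_grayordinates(self) -> int:
        return int(self.maps.shape[1])


def subject_seed_maps(series: GrayordinateSeries, prior: LabelMap) -> np.ndarray:
    """One seed-based correlation map per network of the prior parcellation.

    For each network, the "seed" is the mean time series over its
    grayordinates; the map is that seed's correlation with every grayordinate.
    Returns a (K, G) array in the prior table's label order.  The series is
    expected to be smoothed and motion-censored upstream.
    """
    maps = np.empty((len(prior.table), series.n_grayordinates))
    for row, label_id in enumerate(prior.table.ids):
        roi = prior.indices_of(label_id)
        if roi.size == 0:
            raise ValueError(
                f"prior network {prior.table.name_of(label_id)!r} has no grayordinates"
            )
        maps[row] = seed_map(series, roi).values
    return maps


def average_and_threshold(
    per_subject_maps: list[np.ndarray],
    table: LabelTable,
    sd_multiplier: float = 1.0,
    provenance: dict | None = None,
) -> TemplateSet:
    """Average seed maps across subjects and threshold each network map.

    Per network, grayordinates are kept where the averaged value exceeds
    mean + sd_multiplier * SD of that averaged map over all grayordinates
    (sample SD); others are set to exactly 0.  ``sd_multiplier = -inf``
    disables thresholding.
    """
    if not per_subject_maps:
        raise ValueError("need at least one subject")
    stack = np.stack([np.asarray(m, dtype=float) for m in per_subject_maps])
    if stack.ndim != 3:
        raise ValueError("each subject must contribute a (K, G) map array")
    avg = stack.mean(axis=0)
    out = np.zeros_like(avg)
    for k in range(avg.shape[0]):
        row = avg[k]
        if np.isneginf(sd_multiplier):
            out[k] = row
            continue
        sd = row.std(ddof=1)
        if sd == 0:
            raise ValueError(f"network {table.name_of(table.ids[k])!r} map is constant")
        keep = row > row.mean() + sd_multiplier * sd
        out[k, keep] = row[keep]
    prov = {
        "n_subjects": len(per_subject_maps),
        "threshold_rule": f"mean + {sd_multiplier} * SD (per map, all grayordinates)",
    }
    if provenance:
        prov.update(provenance)
    return TemplateSet(out, table, prov)


def compare_template_sets(a: TemplateSet, b: TemplateSet) -> dict[str, dict]:
    """Per-network Pearson r over shared nonzero grayordinates, plus b - a maps.

    Networks with fewer than 3 shared nonzero grayordinates report r = nan.
    """
    if a.maps.shape != b.maps.shape or a.table != b.table:
        raise ValueError("template sets must share grid size and label table")
    out: dict[str, dict] = {}
    for k, label_id in enumerate(a.table.ids):
        shared = a.support[k] & b.support[k]
        if shared.sum() < 3:
            r = float("nan")
        else:
            r = float(stats.pearsonr(a.maps[k, shared], b.maps[k, shared])[0])
        out[a.table.name_of(label_id)] = {
            "pearson_r": r,
            "n_shared": int(shared.sum()),
            "difference_map": b.maps[k] - a.maps[k],
        }
    return out
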