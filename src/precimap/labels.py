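"""Network label tables and per-grayordinate label maps.

A parcellation assigns every cortical grayordinate to one of a fixed set of
named large-scale networks, or to ``0`` ("unassigned").  The default table
carries the 14 canonical adult resting-state networks used as priors for
individualized mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 14 canonical large-scale resting-state networks, in label-id order.
DEFAULT_NETWORK_NAMES: tuple[str, ...] = (
    "AUD",    # auditory
    "DMN",    # default mode
    "PMN",    # parietal medial
    "SMd",    # sensorimotor dorsal
    "VAN",    # ventral attention
    "CO",     # cingulo-opercular
    "FP",     # frontal parietal
    "PON",    # parietal occipital
    "SMl",    # sensorimotor lateral
    "VIS",    # visual
    "DAN",    # dorsal attention
    "MTL",    # medial temporal
    "Sal",    # salience
    "Tpole",  # temporal pole
)

UNASSIGNED = 0


@dataclass(frozen=True)
class LabelTable:
    """Ordered mapping of positive integer label ids to network names.

    Id ``0`` is reserved for "unassigned" and never appears in the table.
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        names = [n for _, n in self.entries]
        if any(i < 1 for i in ids):
            raise ValueError("label ids must be >= 1 (0 is reserved for unassigned)")
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        if len(set(names)) != len(names):
            raise ValueError("label names must be unique")

    @classmethod
    def default(cls, k: int = 14) -> "LabelTable":
        """Table of the first ``k`` canonical networks (k <= 14)."""
        if not 1 <= k <= len(DEFAULT_NETWORK_NAMES):
            raise ValueError(f"k must be in 1..{len(DEFAULT_NETWORK_NAMES)}, got {k}")
        return cls(tuple((i + 1, DEFAULT_NETWORK_NAMES[i]) for i in range(k)))

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def name_of(self, label_id: int) -> str:
        if label_id == UNASSIGNED:
            return "unassigned"
        for i, n in self.entries:
            if i == label_id:
                return n
        raise KeyError(f"label id {label_id} not in table")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label_id: int) -> bool:
        return label_id in self.ids


@dataclass
class LabelMap:
    """Per-grayordinate network assignment over a fixed label table."""

    labels: np.ndarray  # (G,) integer; 0 = unassigned
    table: LabelTable = field(default_factory=LabelTable.default)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        present = set(np.unique(self.labels).tolist())
        allowed = {UNASSIGNED, *self.table.ids}
        stray = present - allowed
        if stray:
            raise ValueError(f"label ids {sorted(stray)} absent from the label table")

    @property
    def n_grayordinates(self) -> int:
        return int(self.labels.size)

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask of grayordinates carrying a network label."""
        return self.labels != UNASSIGNED

    def indices_of(self, label_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label_id)

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return self.table == other.table and np.array_equal(self.labels, other.labels)
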