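"""Plain-text interchange formats, run configuration, and optional CIFTI-2.

TSV and JSON are the canonical formats so the package runs with no
neuroimaging dependency; CIFTI-2 dtseries/dlabel export is available when
nibabel is installed.  Grayordinate indices are 0-based everywhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .consensus import DEFAULT_TIE_DENSITIES
from .labels import LabelMap, LabelTable
from .surface import SurfaceMesh
from .templates import TemplateSet
from .timeseries import GrayordinateSeries


@dataclass
class RunConfig:
    """All pipeline parameters with their canonical defaults.

    Defaults are the published operating point of the method: FD threshold
    0.3 mm, 2.25 mm smoothing kernel, 1-SD template threshold, tie densities
    0.3-3.0%, 20 mm exclusion, 400-grayordinate network filter,
    30-grayordinate region filter, Jaccard 0.2.
    """

    fd_threshold: float = 0.3
    sigma_mm: float = 2.25
    smoothing_is_sigma: bool = True
    sd_multiplier: float = 1.0
    threshold_reference: str = "per_map_all_grayordinates"
    densities: tuple[float, ...] = DEFAULT_TIE_DENSITIES
    exclusion_mm: float = 20.0
    min_network: int = 400
    min_region: int = 30
    jaccard_threshold: float = 0.2
    nmi_normalization: str = "arithmetic"
    min_retained_minutes: float = 20.0
    minutes_grid: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0, 25.0)
    repetitions: int = 10
    eta_domain: str = "all"
    standardize_before_seed: bool = False
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["densities"] = tuple(raw.get("densities", DEFAULT_TIE_DENSITIES))
        raw["minutes_grid"] = tuple(raw.get("minutes_grid", (1, 5, 10, 15, 25)))
        return cls(**raw)


# --------------------------------------------------------------------------
# series / fd / mask TSV
# --------------------------------------------------------------------------

def write_series(series: GrayordinateSeries, path: str | Path) -> None:
    """Frames x grayordinates TSV with a '# tr=<s>' comment and the mask
    folded into a trailing 'retained' column."""
    path = Path(path)
    g = series.n_grayordinates
    with path.open("w") as fh:
        fh.write(f"# tr={series.tr}\n")
        fh.write("\t".join([f"g{k}" for k in range(g)] + ["retained"]) + "\n")
        for t in range(series.n_frames):
            row = "\t".join(f"{v:.8g}" for v in series.data[t])
            fh.write(f"{row}\t{int(series.retained[t])}\n")


def read_series(path: str | Path) -> GrayordinateSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("# tr="):
        raise ValueError(f"{path}: missing '# tr=' header line")
    tr = float(first.split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#")
    retained = frame.pop("retained").to_numpy(dtype=bool)
    return GrayordinateSeries(frame.to_numpy(dtype=float), tr, retained)


def write_fd(fd: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(fd, dtype=float), fmt="%.6g")


def read_fd(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=1)


# --------------------------------------------------------------------------
# label maps
# --------------------------------------------------------------------------

def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """TSV: '#label <id> <name>' table lines, then grayordinate_index/label_id."""
    path = Path(path)
    with path.open("w") as fh:
        for lid, name in label_map.table.entries:
            fh.write(f"#label\t{lid}\t{name}\n")
        fh.write("grayordinate_index\tlabel_id\n")
        for g, lab in enumerate(label_map.labels):
            fh.write(f"{g}\t{int(lab)}\n")


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    entries: list[tuple[int, str]] = []
    rows: list[tuple[int, int]] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#label\t"):
                _, lid, name = line.split("\t")
                entries.append((int(lid), name))
                continue
            if line.startswith("grayordinate_index"):
                continue
            parts = line.split("\t")
            try:
                rows.append((int(parts[0]), int(parts[1])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{line_no}: malformed row {line!r}") from exc
    if not entries:
        raise ValueError(f"{path}: no '#label' table lines found")
    table = LabelTable(tuple(entries))
    labels = np.zeros(len(rows), dtype=np.int64)
    for line_rank, (g, lab) in enumerate(rows):
        if not 0 <= g < len(rows):
            raise ValueError(f"{path}: grayordinate index {g} out of range")
        labels[g] = lab
    return LabelMap(labels, table)   # stray label ids rejected by LabelMap


# --------------------------------------------------------------------------
# meshes and templates
# --------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    payload = {
        "coordinates": mesh.coordinates.tolist(),
        "edges": [[i, j, w] for i, j, w in mesh.edges],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_mesh(path: str | Path) -> SurfaceMesh:
    payload = json.loads(Path(path).read_text())
    coords = np.asarray(payload["coordinates"], dtype=float)
    n = coords.shape[0]
    edges = payload["edges"]
    if edges:
        i = np.array([e[0] for e in edges])
        j = np.array([e[1] for e in edges])
        w = np.array([e[2] for e in edges], dtype=float)
        adj = sparse.coo_matrix((w, (i, j)), shape=(n, n))
        adj = (adj + adj.T).tocsr()
    else:
        adj = sparse.csr_matrix((n, n))
    return SurfaceMesh(coords, adj)


def write_templates(templates: TemplateSet, directory: str | Path) -> None:
    """Directory with maps.tsv (K rows x G cols) and meta.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "maps.tsv", templates.maps, delimiter="\t", fmt="%.8g")
    meta = {
        "labels": [[lid, name] for lid, name in templates.table.entries],
        "provenance": templates.provenance,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_templates(directory: str | Path) -> TemplateSet:
    directory = Path(directory)
    maps = np.loadtxt(directory / "maps.tsv", delimiter="\t", ndmin=2)
    meta = json.loads((directory / "meta.json").read_text())
    table = LabelTable(tuple((int(l), n) for l, n in meta["labels"]))
    return TemplateSet(maps, table, meta.get("provenance", {}))


# --------------------------------------------------------------------------
# cohort directory layout
# --------------------------------------------------------------------------

def write_cohort(cohort, directory: str | Path) -> None:
    """Persist a simulated cohort: mesh, group truth, per-subject files,
    and a manifest JSON tying them together."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mesh(cohort.mesh, directory / "mesh.json")
    write_label_map(cohort.group_truth, directory / "group_truth.tsv")
    manifest = {
        "config": _config_dict(cohort.config),
        "subjects": [],
    }
    for sub in cohort.subjects:
        prefix = directory / sub.subject_id
        write_series(sub.series, Path(f"{prefix}_series.tsv"))
        write_fd(sub.fd, Path(f"{prefix}_fd.tsv"))
        write_label_map(sub.truth, Path(f"{prefix}_truth.tsv"))
        manifest["subjects"].append(sub.subject_id)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    coupling = d.get("coupling")
    if coupling is not None:
        d["coupling"] = np.asarray(coupling["coupling"]).tolist()
    return d


# --------------------------------------------------------------------------
# optional CIFTI-2 layer
# --------------------------------------------------------------------------

def _require_nibabel():
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "CIFTI-2 support requires nibabel (install the 'neuro' extra)"
        ) from exc
    return nib


def _brain_model_axis(n: int):
    nib = _require_nibabel()
    return nib.cifti2.BrainModelAxis.from_mask(
        np.ones(n, dtype=bool), name="CIFTI_STRUCTURE_CORTEX_LEFT"
    )


def write_dtseries(series: GrayordinateSeries, path: str | Path) -> None:
    """Export as CIFTI-2 dtseries (all grayordinates on a synthetic left
    cortex surface structure).  The retention mask is not representable in
    dtseries and must be carried separately."""
    nib = _require_nibabel()
    series_axis = nib.cifti2.SeriesAxis(start=0.0, step=series.tr,
                                        size=series.n_frames, unit="SECOND")
    header = nib.cifti2.Cifti2Header.from_axes(
        (series_axis, _brain_model_axis(series.n_grayordinates))
    )
    nib.save(nib.cifti2.Cifti2Image(series.data, header=header), str(path))


def read_dtseries(path: str | Path) -> GrayordinateSeries:
    nib = _require_nibabel()
    img = nib.load(str(path))
    series_axis = img.header.get_axis(0)
    return GrayordinateSeries(np.asarray(img.get_fdata()), float(series_axis.step))


def write_dlabel(label_map: LabelMap, path: str | Path) -> None:
    nib = _require_nibabel()
    label_dict = {0: ("unassigned", (0.0, 0.0, 0.0, 0.0))}
    rng = np.random.default_rng(0)
    for lid, name in label_map.table.entries:
        r, g, b = rng.random(3)
        label_dict[lid] = (name, (float(r), float(g), float(b), 1.0))
    label_axis = nib.cifti2.LabelAxis(["networks"], label_dict)
    header = nib.cifti2.Cifti2Header.from_axes(
        (label_axis, _brain_model_axis(label_map.n_grayordinates))
    )
    data = label_map.labels[np.newaxis, :].astype(float)
    nib.save(nib.cifti2.Cifti2Image(data, header=header), str(path))


def read_dlabel(path: str | Path) -> LabelMap:
    nib = _require_nibabel()
    img = nib.load(str(path))
    label_axis = img.header.get_axis(0)
    table_dict = label_axis.label[0]
    entries = tuple(
        (int(k), v[0]) for k, v in sorted(table_dict.items()) if int(k) != 0
    )
    labels = np.asarray(img.get_fdata()[0], dtype=np.int64)
    return LabelMap(labels, LabelTable(entries))
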