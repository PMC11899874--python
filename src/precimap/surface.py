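"""Toy cortical surface meshes with geodesic distances.

The real analyses run on a subject's midthickness surface; here a small
connected mesh (regular grid or icosphere) stands in for it.  Geodesic
distances along mesh edges drive surface-constrained Gaussian smoothing and
the short-distance exclusion rule used before community detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra


@dataclass(frozen=True)
class SurfaceMesh:
    """Undirected mesh graph: node coordinates plus edge lengths in mm."""

    coordinates: np.ndarray          # (n, 3) synthetic embedding, mm
    adjacency: sparse.csr_matrix     # symmetric; entry (i, j) = edge length mm

    def __post_init__(self) -> None:
        n = self.coordinates.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match coordinate count")
        if self.adjacency.nnz and self.adjacency.data.min() <= 0:
            raise ValueError("edge lengths must be strictly positive")
        n_comp, _ = connected_components(self.adjacency, directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh must be connected ({n_comp} components found)")

    @property
    def node_count(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        """Unique undirected edges as (i, j, length_mm) with i < j."""
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return [(int(i), int(j), float(w)) for i, j, w in zip(coo.row, coo.col, coo.data)]

    def neighbors(self, node: int) -> np.ndarray:
        row = self.adjacency.getrow(node)
        return row.indices

    def geodesic_distances(self, sources=None, limit: float = np.inf) -> np.ndarray:
        """Shortest-path (geodesic) distances along mesh edges.

        Parameters
        ----------
        sources
            Node indices to start from; all nodes if None.
        limit
            Stop exploring beyond this distance (entries become +inf).
        """
        return dijkstra(self.adjacency, directed=False, indices=sources, limit=limit)


def build_toy_surface(
    n_grayordinates: int, geometry: str = "grid", spacing: float = 1.0
) -> SurfaceMesh:
    """Construct a deterministic toy mesh with ``n_grayordinates`` nodes.

    ``grid`` builds the most square rows x cols 4-neighbour lattice whose node
    count is exactly n (a prime n degrades to a path).  ``icosphere`` builds a
    subdivided icosahedron, which only exists for n in {12, 42, 162, 642, ...};
    other n raise.  ``spacing`` is the (mean) edge length in mm.
    """
    if n_grayordinates < 4:
        raise ValueError("need at least 4 grayordinates to build a surface")
    if geometry == "grid":
        return _grid_mesh(n_grayordinates, spacing)
    if geometry == "icosphere":
        return _icosphere_mesh(n_grayordinates, spacing)
    raise ValueError(f"unknown geometry {geometry!r}; choose 'grid' or 'icosphere'")


def _grid_mesh(n: int, spacing: float) -> SurfaceMesh:
    rows = int(np.sqrt(n))
    while n % rows:
        rows -= 1
    cols = n // rows
    idx = np.arange(n).reshape(rows, cols)
    src, dst = [], []
    src.extend(idx[:, :-1].ravel()); dst.extend(idx[:, 1:].ravel())   # horizontal
    src.extend(idx[:-1, :].ravel()); dst.extend(idx[1:, :].ravel())   # vertical
    src, dst = np.array(src), np.array(dst)
    data = np.full(src.size, spacing)
    adj = sparse.coo_matrix((data, (src, dst)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    rr, cc = np.divmod(np.arange(n), cols)
    coords = np.column_stack([cc * spacing, rr * spacing, np.zeros(n)])
    return SurfaceMesh(coords, adj)


def _icosphere_sizes(max_sub: int = 8) -> list[int]:
    return [10 * 4**s + 2 for s in range(max_sub + 1)]


def _icosphere_mesh(n: int, spacing: float) -> SurfaceMesh:
    sizes = _icosphere_sizes()
    if n not in sizes:
        raise ValueError(
            f"icosphere geometry requires a node count in {sizes[:6]}...; got {n}"
        )
    import trimesh

    sub = sizes.index(n)
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    coords = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces)
    pairs = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    pairs.sort(axis=1)
    pairs = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    scale = spacing / lengths.mean()     # mean edge length -> spacing mm
    coords *= scale
    lengths *= scale
    adj = sparse.coo_matrix(
        (lengths, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    adj = (adj + adj.T).tocsr()
    return SurfaceMesh(coords, adj)


def gaussian_smoothing_weights(
    mesh: SurfaceMesh, sigma_mm: float, truncate: float = 3.0
) -> sparse.csr_matrix:
    """Row-normalized geodesic Gaussian kernel, truncated at ``truncate``·sigma.

    Row g holds the weights with which neighbouring grayordinates contribute
    to the smoothed value at g; each row sums to 1.  sigma 0 gives identity.
    """
    n = mesh.node_count
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return sparse.identity(n, format="csr")
    radius = truncate * sigma_mm
    dist = mesh.geodesic_distances(limit=radius)
    rows, cols = np.nonzero(np.isfinite(dist))
    w = np.exp(-(dist[rows, cols] ** 2) / (2.0 * sigma_mm**2))
    kernel = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    row_sums = np.asarray(kernel.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / row_sums)
    return (inv @ kernel).tocsr()
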