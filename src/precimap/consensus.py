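"""Data-driven network mapping by tie-density community-detection consensus.

The comparison arm to template matching: from a dense connectivity matrix,
(1) exclude short-range pairs (geodesic distance <= 20 mm) to control for
spatial smoothing, (2) keep the strongest connections at a range of tie
densities (0.3-3.0% of admissible pairs), (3) detect communities on each
thresholded graph with a flow-based (map-equation) optimizer, (4) drop
networks smaller than 400 grayordinates, (5) stack the density maps from
most stringent to most lenient into a consensus map, (6) absorb contiguous
regions smaller than 30 grayordinates into their largest neighbor, and
(7) rename the anonymous communities by Jaccard overlap (threshold 0.2)
with a reference parcellation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix, dense_connectivity
from .labels import LabelMap, LabelTable, UNASSIGNED
from .surface import SurfaceMesh, gaussian_smoothing_weights
from .timeseries import GrayordinateSeries, censor_frames, smooth_series

logger = logging.getLogger(__name__)

#: Tie densities used for the consensus, most stringent first (fractions).
DEFAULT_TIE_DENSITIES: tuple[float, ...] = (
    0.003, 0.004, 0.005, 0.010, 0.015, 0.020, 0.025, 0.030
)


@dataclass
class ConsensusConfig:
    """Parameters of the community-consensus pipeline."""

    densities: tuple[float, ...] = DEFAULT_TIE_DENSITIES
    exclusion_mm: float = 20.0
    min_network: int = 400
    min_region: int = 30
    jaccard_threshold: float = 0.2
    backend: str = "greedy-mapeq"
    seed: int = 0

    def __post_init__(self) -> None:
        d = tuple(self.densities)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        if min(d) <= 0 or max(d) > 1:
            raise ValueError("densities must be fractions in (0, 1]")
        for name in ("min_network", "min_region"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.densities = d


@dataclass
class AdmissiblePairs:
    """Upper-triangle grayordinate pairs surviving the distance exclusion."""

    i: np.ndarray
    j: np.ndarray
    n_nodes: int
    excluded_pairs: int

    def __len__(self) -> int:
        return int(self.i.size)


@dataclass
class TieDensityGraph:
    """The strongest admissible connections at one tie density."""

    n_nodes: int
    i: np.ndarray            # edge endpoints, i < j
    j: np.ndarray
    weight: np.ndarray
    density: float
    excluded_pairs: int

    @property
    def n_edges(self) -> int:
        return int(self.i.size)


def apply_distance_exclusion(
    conn: ConnectivityMatrix, mesh: SurfaceMesh, exclusion_mm: float = 20.0
) -> AdmissiblePairs:
    """Admissible pairs: geodesic distance strictly greater than the exclusion."""
    g = conn.n_grayordinates
    if mesh.node_count != g:
        raise ValueError("mesh node count must equal connectivity size")
    dist = mesh.geodesic_distances()
    iu, ju = np.triu_indices(g, k=1)
    keep = dist[iu, ju] > exclusion_mm
    return AdmissiblePairs(iu[keep], ju[keep], g, int((~keep).sum()))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def threshold_by_tie_density(
    conn: ConnectivityMatrix, admissible: AdmissiblePairs, density: float
) -> TieDensityGraph:
    """Keep the top round(density * |admissible|) pairs by connectivity weight.

    Ties at the cut are broken by (i, j) lexicographic order (and logged).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be a fraction in (0, 1]")
    n_adm = len(admissible)
    if n_adm == 0:
        raise ValueError("no admissible pairs after distance exclusion")
    w = conn.values[admissible.i, admissible.j]
    n_keep = _round_half_up(density * n_adm)
    order = np.lexsort((admissible.j, admissible.i, -w))
    kept = order[:n_keep]
    if n_keep and n_keep < n_adm and w[order[n_keep - 1]] == w[order[n_keep]]:
        logger.info("tie-density %.4f: weight tie at the cut broken lexicographically",
                    density)
    return TieDensityGraph(
        admissible.n_nodes,
        admissible.i[kept], admissible.j[kept], w[kept],
        density, admissible.excluded_pairs,
    )


# --------------------------------------------------------------------------
# community detection backends
# --------------------------------------------------------------------------

def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(x > 0, x * np.log2(np.maximum(x, 1e-300)), 0.0)


class _MapEquation:
    """Two-level map-equation codelength bookkeeping for local node moves."""

    def __init__(self, n: int, i: np.ndarray, j: np.ndarray, w: np.ndarray,
                 self_loops: np.ndarray | None = None) -> None:
        self.n = n
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        for a, b, ww in zip(i, j, w):
            a, b = int(a), int(b)
            self.adj[a][b] = self.adj[a].get(b, 0.0) + float(ww)
            self.adj[b][a] = self.adj[b].get(a, 0.0) + float(ww)
        self.self_loop = np.zeros(n) if self_loops is None else np.asarray(self_loops,
                                                                           dtype=float)
        self.deg_ext = np.array([sum(d.values()) for d in self.adj])
        self.strength = self.deg_ext + 2.0 * self.self_loop
        self.two_w = float(self.strength.sum())
        if self.two_w == 0:
            raise ValueError("graph has no edges")
        self.module = np.arange(n)
        self.p = self.strength / self.two_w           # per-module visit rates
        self.exit = self.deg_ext / self.two_w         # per-module exit rates
        self.q = float(self.exit.sum())

    def _delta(self, alpha: int, src: int, dst: int,
               w_src: float, w_dst: float) -> float:
        """Codelength change for moving node alpha from module src to dst."""
        p_a = self.strength[alpha] / self.two_w
        e_a = self.deg_ext[alpha] / self.two_w
        q_src_new = self.exit[src] - e_a + 2.0 * w_src / self.two_w
        q_dst_new = self.exit[dst] + e_a - 2.0 * w_dst / self.two_w
        p_src_new = self.p[src] - p_a
        p_dst_new = self.p[dst] + p_a
        q_new = self.q - self.exit[src] - self.exit[dst] + q_src_new + q_dst_new
        delta = (
            _plogp(q_new) - _plogp(self.q)
            - 2 * (_plogp(q_src_new) + _plogp(q_dst_new)
                   - _plogp(self.exit[src]) - _plogp(self.exit[dst]))
            + _plogp(q_src_new + p_src_new) + _plogp(q_dst_new + p_dst_new)
            - _plogp(self.exit[src] + self.p[src])
            - _plogp(self.exit[dst] + self.p[dst])
        )
        return float(delta)

    def _apply(self, alpha: int, src: int, dst: int,
               w_src: float, w_dst: float) -> None:
        p_a = self.strength[alpha] / self.two_w
        e_a = self.deg_ext[alpha] / self.two_w
        new_src = self.exit[src] - e_a + 2.0 * w_src / self.two_w
        new_dst = self.exit[dst] + e_a - 2.0 * w_dst / self.two_w
        self.q += new_src + new_dst - self.exit[src] - self.exit[dst]
        self.exit[src], self.exit[dst] = new_src, new_dst
        self.p[src] -= p_a
        self.p[dst] += p_a
        self.module[alpha] = dst

    def optimize(self, rng: np.random.Generator, max_passes: int = 30) -> bool:
        """Repeated node-move passes until no move improves the codelength."""
        improved_any = False
        order = np.arange(self.n)
        for _ in range(max_passes):
            rng.shuffle(order)
            n_moves = 0
            for alpha in order:
                src = int(self.module[alpha])
                mod_w: dict[int, float] = {}
                for nbr, ww in self.adj[alpha].items():
                    m = int(self.module[nbr])
                    mod_w[m] = mod_w.get(m, 0.0) + ww
                w_src = mod_w.get(src, 0.0)
                best_dst, best_delta = src, 0.0
                for dst, w_dst in mod_w.items():
                    if dst == src:
                        continue
                    d = self._delta(alpha, src, dst, w_src, w_dst)
                    if d < best_delta - 1e-12:
                        best_dst, best_delta = dst, d
                if best_dst != src:
                    self._apply(alpha, src, best_dst, w_src, mod_w[best_dst])
                    n_moves += 1
            if n_moves == 0:
                break
            improved_any = True
        return improved_any


def _mapequation_partition(n: int, i: np.ndarray, j: np.ndarray, w: np.ndarray,
                           seed: int) -> np.ndarray:
    """Seeded greedy two-level map-equation optimizer (Louvain-style passes
    with aggregation), returning a module index per node (-1 for isolated)."""
    rng = np.random.default_rng(seed)
    membership = np.arange(n)
    cur_n, ci, cj, cw = n, i, j, w
    self_loops = None
    for _level in range(20):
        me = _MapEquation(cur_n, ci, cj, cw, self_loops)
        improved = me.optimize(rng)
        mods, compact = np.unique(me.module, return_inverse=True)
        membership = compact[membership]
        if not improved or mods.size == cur_n:
            break
        # aggregate: modules become super-nodes; internal weight -> self-loops
        src_m, dst_m = compact[ci], compact[cj]
        new_n = mods.size
        agg_self = np.zeros(new_n)
        inter: dict[tuple[int, int], float] = {}
        internal = src_m == dst_m
        np.add.at(agg_self, src_m[internal], cw[internal])
        if self_loops is not None:
            np.add.at(agg_self, compact, self_loops)
        for a, b, ww in zip(src_m[~internal], dst_m[~internal], cw[~internal]):
            key = (int(min(a, b)), int(max(a, b)))
            inter[key] = inter.get(key, 0.0) + float(ww)
        if inter:
            keys = np.array(sorted(inter))
            ci, cj = keys[:, 0], keys[:, 1]
            cw = np.array([inter[tuple(k)] for k in keys])
        else:
            ci = cj = np.array([], dtype=int)
            cw = np.array([])
        cur_n, self_loops = new_n, agg_self
        if ci.size == 0:
            break
    # isolated nodes (no incident edges) are not communities
    has_edge = np.zeros(n, dtype=bool)
    has_edge[i] = True
    has_edge[j] = True
    membership[~has_edge] = -1
    return membership


def _igraph_infomap_partition(n: int, i: np.ndarray, j: np.ndarray, w: np.ndarray,
                              seed: int) -> np.ndarray:
    import random

    import igraph

    igraph.set_random_number_generator(random.Random(int(seed)))
    graph = igraph.Graph(n=n, edges=list(zip(i.tolist(), j.tolist())))
    clustering = graph.community_infomap(edge_weights=w.tolist(), trials=5)
    membership = np.asarray(clustering.membership)
    has_edge = np.zeros(n, dtype=bool)
    has_edge[i] = True
    has_edge[j] = True
    membership[~has_edge] = -1
    return membership


_BACKENDS = {
    "greedy-mapeq": _mapequation_partition,
    "igraph-infomap": _igraph_infomap_partition,
}


def detect_communities(
    graph: TieDensityGraph, backend: str = "greedy-mapeq", seed: int = 0
) -> LabelMap:
    """Partition the tie-density graph into anonymous integer communities.

    Communities are renumbered 1..C by decreasing size; nodes with no edges
    are labeled 0 (unassigned).  The reference backend is deterministic under
    the seed.
    """
    if backend not in _BACKENDS:
        raise ValueError(
            f"unknown backend {backend!r}; available: {sorted(_BACKENDS)}"
        )
    if graph.n_edges == 0:
        raise ValueError("tie-density graph has no edges")
    membership = _BACKENDS[backend](
        graph.n_nodes, graph.i, graph.j, graph.weight, seed
    )
    labels = np.zeros(graph.n_nodes, dtype=np.int64)
    mods = [m for m in np.unique(membership) if m >= 0]
    sizes = {m: int((membership == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], int(np.argmax(membership == m))))
    for new_id, m in enumerate(order, start=1):
        labels[membership == m] = new_id
    table = LabelTable(tuple((lid, f"community-{lid}") for lid in
                             range(1, len(order) + 1)))
    return LabelMap(labels, table)


# --------------------------------------------------------------------------
# filtering, consensus, relabeling
# --------------------------------------------------------------------------

def size_filter(labels: LabelMap, min_network: int = 400) -> LabelMap:
    """Relabel networks with fewer than ``min_network`` grayordinates to 0."""
    out = labels.labels.copy()
    for lid in labels.table.ids:
        if 0 < (out == lid).sum() < min_network:
            out[out == lid] = UNASSIGNED
    return LabelMap(out, labels.table)


def _greedy_jaccard_pairs(
    cand_labels: np.ndarray, cand_ids, ref_labels: np.ndarray, ref_ids
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of candidate to reference labels by Jaccard."""
    scored = []
    for c in cand_ids:
        a = cand_labels == c
        if not a.any():
            continue
        for r in ref_ids:
            b = ref_labels == r
            union = np.logical_or(a, b).sum()
            if union == 0:
                continue
            jac = np.logical_and(a, b).sum() / union
            scored.append((float(jac), int(c), int(r)))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c, used_r, pairs = set(), set(), []
    for jac, c, r in scored:
        if c in used_c or r in used_r:
            continue
        used_c.add(c)
        used_r.add(r)
        pairs.append((c, r, jac))
    return pairs


def _harmonize_to(target: LabelMap, reference_labels: np.ndarray) -> np.ndarray:
    """Rename the target's anonymous labels to best-Jaccard reference labels;
    unmatched target communities receive fresh ids above the reference range."""
    ref_ids = [r for r in np.unique(reference_labels) if r != UNASSIGNED]
    cand_ids = [c for c in np.unique(target.labels) if c != UNASSIGNED]
    pairs = _greedy_jaccard_pairs(target.labels, cand_ids, reference_labels, ref_ids)
    mapping = {c: r for c, r, jac in pairs if jac > 0}
    next_id = int(max(ref_ids, default=0)) + 1
    out = np.zeros_like(target.labels)
    for c in cand_ids:
        if c in mapping:
            out[target.labels == c] = mapping[c]
        else:
            out[target.labels == c] = next_id
            next_id += 1
    return out


def consensus_across_densities(maps: list[LabelMap]) -> LabelMap:
    """Stack per-density maps, most stringent first: a grayordinate takes its
    label from the first map that assigns it.

    Anonymous labels are made comparable across densities by Jaccard-matching
    each map's communities to the running consensus before filling in.  A
    grayordinate stays 0 only if unassigned at every density.
    """
    if not maps:
        raise ValueError("need at least one density map")
    g = maps[0].n_grayordinates
    consensus = maps[0].labels.copy()
    for m in maps[1:]:
        if m.n_grayordinates != g:
            raise ValueError("density maps must share the grayordinate grid")
        harmonized = _harmonize_to(m, consensus)
        fill = (consensus == UNASSIGNED) & (harmonized != UNASSIGNED)
        consensus[fill] = harmonized[fill]
    ids = [int(v) for v in np.unique(consensus) if v != UNASSIGNED]
    table = LabelTable(tuple((lid, f"community-{lid}") for lid in ids))
    return LabelMap(consensus, table)


def _clusters(labels: np.ndarray, mesh: SurfaceMesh) -> list[np.ndarray]:
    """Mesh-contiguous same-label clusters, as arrays of node indices."""
    n = labels.size
    seen = np.zeros(n, dtype=bool)
    adj = mesh.adjacency
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        lab = labels[start]
        stack, members = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            members.append(node)
            nbrs = adj.indices[adj.indptr[node] : adj.indptr[node + 1]]
            for nb in nbrs:
                if not seen[nb] and labels[nb] == lab:
                    seen[nb] = True
                    stack.append(int(nb))
        clusters.append(np.array(members))
    return clusters


def enforce_min_region(
    labels: LabelMap, mesh: SurfaceMesh, min_region: int = 30
) -> LabelMap:
    """Absorb contiguous network clusters smaller than ``min_region`` into the
    neighboring label with the largest adjacent-cluster grayordinate count.

    Reassignments are applied smallest-cluster-first and the pass repeats
    until a fixed point (absorption can itself create sub-threshold clusters).
    Unassigned (0) clusters are left alone.
    """
    out = labels.labels.copy()
    adj = mesh.adjacency
    for _ in range(labels.n_grayordinates):  # fixed-point iteration guard
        clusters = _clusters(out, mesh)
        small = [c for c in clusters
                 if out[c[0]] != UNASSIGNED and c.size < min_region]
        if not small:
            break
        cluster = min(small, key=lambda c: (c.size, int(c.min())))
        # total adjacent grayordinate count per neighboring label
        neighbor_count: dict[int, int] = {}
        member_set = set(cluster.tolist())
        touching: set[int] = set()
        for node in cluster:
            nbrs = adj.indices[adj.indptr[node] : adj.indptr[node + 1]]
            for nb in nbrs:
                if int(nb) not in member_set:
                    touching.add(int(nb))
        touched_labels = {int(out[nb]) for nb in touching}
        for other in clusters:
            if int(out[other[0]]) in touched_labels and any(
                int(x) in touching for x in other
            ):
                lab = int(out[other[0]])
                if lab != int(out[cluster[0]]):
                    neighbor_count[lab] = neighbor_count.get(lab, 0) + other.size
        candidates = {k: v for k, v in neighbor_count.items() if k != UNASSIGNED}
        if not candidates:
            candidates = neighbor_count
        if not candidates:
            break
        new_label = min(candidates, key=lambda k: (-candidates[k], k))
        out[cluster] = new_label
    return LabelMap(out, labels.table)


def relabel_by_jaccard(
    labels: LabelMap, reference: LabelMap, threshold: float = 0.2
) -> LabelMap:
    """Rename anonymous communities to the reference networks they overlap.

    Candidate (community, reference-network) pairs are scored by Jaccard
    similarity and accepted greedily (each side used once) while J >= the
    threshold; unmatched communities become unassigned (0).
    """
    if labels.n_grayordinates != reference.n_grayordinates:
        raise ValueError("label maps must share the grayordinate grid")
    cand_ids = [c for c in np.unique(labels.labels) if c != UNASSIGNED]
    pairs = _greedy_jaccard_pairs(
        labels.labels, cand_ids, reference.labels, reference.table.ids
    )
    mapping = {c: r for c, r, jac in pairs if jac >= threshold}
    out = np.zeros_like(labels.labels)
    for c, r in mapping.items():
        out[labels.labels == c] = r
    return LabelMap(out, reference.table)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

class ConsensusMapper:
    """Single-subject community-consensus mapping as a reusable callable.

    smooth -> censor -> dense connectivity -> distance exclusion -> per-density
    thresholding + community detection + size filter -> stringent-to-lenient
    consensus -> minimum-region cleanup -> Jaccard relabeling to the reference.
    The distance exclusion and smoothing weights are precomputed per mesh.
    """

    def __init__(
        self,
        mesh: SurfaceMesh,
        reference: LabelMap,
        config: ConsensusConfig | None = None,
        sigma_mm: float = 2.25,
        fd_threshold: float = 0.3,
    ) -> None:
        self.mesh = mesh
        self.reference = reference
        self.config = config or ConsensusConfig()
        self.sigma_mm = sigma_mm
        self.fd_threshold = fd_threshold
        self._weights = (
            gaussian_smoothing_weights(mesh, sigma_mm) if sigma_mm > 0 else None
        )
        self._admissible: AdmissiblePairs | None = None

    def label_connectivity(self, conn: ConnectivityMatrix) -> LabelMap:
        cfg = self.config
        if self._admissible is None:
            self._admissible = apply_distance_exclusion(
                conn, self.mesh, cfg.exclusion_mm
            )
        density_maps = []
        for d_idx, density in enumerate(cfg.densities):
            graph = threshold_by_tie_density(conn, self._admissible, density)
            communities = detect_communities(
                graph, backend=cfg.backend, seed=cfg.seed + d_idx
            )
            density_maps.append(size_filter(communities, cfg.min_network))
        consensus = consensus_across_densities(density_maps)
        consensus = enforce_min_region(consensus, self.mesh, cfg.min_region)
        return relabel_by_jaccard(consensus, self.reference, cfg.jaccard_threshold)

    def __call__(
        self, series: GrayordinateSeries, fd: np.ndarray | None = None
    ) -> LabelMap:
        if self.sigma_mm > 0:
            series = smooth_series(series, self.mesh, self.sigma_mm,
                                   weights=self._weights)
        if fd is not None:
            series = censor_frames(series, fd, self.fd_threshold)
        return self.label_connectivity(dense_connectivity(series))
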