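import numpy as np
import pytest

import precimap as pm
from precimap.connectivity import ConnectivityMatrix
from precimap.consensus import AdmissiblePairs
from precimap.labels import LabelMap, LabelTable


def planted_block_graph(n_blocks=4, block_size=30, p_in=0.9, p_out=0.01, seed=0):
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    truth = np.repeat(np.arange(1, n_blocks + 1), block_size)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(truth[iu] == truth[ju], p_in, p_out)
    keep = rng.random(iu.size) < p
    i, j = iu[keep], ju[keep]
    graph = pm.TieDensityGraph(n, i, j, np.ones(i.size), 0.1, 0)
    return graph, truth


class TestDistanceExclusion:
    def test_zero_exclusion_keeps_all_offdiagonal_pairs(self, path5):
        conn = ConnectivityMatrix(np.eye(5), 10)
        adm = pm.apply_distance_exclusion(conn, path5, 0.0)
        assert len(adm) == 10

    def test_short_mesh_excludes_everything(self):
        mesh = pm.build_toy_surface(4, "grid", spacing=10.0)  # 2x2, 10 mm edges
        conn = ConnectivityMatrix(np.eye(4), 10)
        adm = pm.apply_distance_exclusion(conn, mesh, 20.0)
        assert len(adm) == 0  # max geodesic distance is 20 mm, rule is strict

    def test_path_graph_matches_shortest_path_oracle(self, path5):
        conn = ConnectivityMatrix(np.eye(5), 10)
        adm = pm.apply_distance_exclusion(conn, path5, 2.0)
        expected = {(i, j) for i in range(5) for j in range(i + 1, 5) if j - i >= 3}
        assert set(zip(adm.i.tolist(), adm.j.tolist())) == expected


class TestTieDensity:
    def _full_admissible(self, n):
        iu, ju = np.triu_indices(n, k=1)
        return AdmissiblePairs(iu, ju, n, 0)

    def test_round_half_up_edge_count(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, (100, 100))
        conn = ConnectivityMatrix((c + c.T) / 2, 10)
        graph = pm.threshold_by_tie_density(conn, self._full_admissible(100), 0.003)
        assert graph.n_edges == 15  # round(0.003 * 4950) = round(14.85)

    def test_density_one_keeps_all(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(-1, 1, (20, 20))
        conn = ConnectivityMatrix((c + c.T) / 2, 10)
        graph = pm.threshold_by_tie_density(conn, self._full_admissible(20), 1.0)
        assert graph.n_edges == 190

    def test_kept_weights_dominate_dropped(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(-1, 1, (40, 40))
        conn = ConnectivityMatrix((c + c.T) / 2, 10)
        adm = self._full_admissible(40)
        graph = pm.threshold_by_tie_density(conn, adm, 0.1)
        all_w = conn.values[adm.i, adm.j]
        kept = set(zip(graph.i.tolist(), graph.j.tolist()))
        dropped_w = [w for i, j, w in zip(adm.i, adm.j, all_w)
                     if (int(i), int(j)) not in kept]
        assert graph.weight.min() >= max(dropped_w)

    def test_zero_admissible_errors(self):
        conn = ConnectivityMatrix(np.eye(4), 10)
        empty = AdmissiblePairs(np.array([], int), np.array([], int), 4, 6)
        with pytest.raises(ValueError):
            pm.threshold_by_tie_density(conn, empty, 0.5)


class TestDetectCommunities:
    def test_two_disconnected_cliques(self):
        n = 20
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(i, j) for i in range(10, 20) for j in range(i + 1, 20)]
        i = np.array([e[0] for e in edges]); j = np.array([e[1] for e in edges])
        graph = pm.TieDensityGraph(n, i, j, np.ones(i.size), 0.1, 0)
        labels = pm.detect_communities(graph, seed=0)
        assert len(np.unique(labels.labels)) == 2
        assert len(set(labels.labels[:10])) == 1
        assert len(set(labels.labels[10:])) == 1

    def test_deterministic_under_seed(self):
        graph, _ = planted_block_graph(seed=3)
        a = pm.detect_communities(graph, seed=5)
        b = pm.detect_communities(graph, seed=5)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_partition_recovery(self, seed):
        graph, truth = planted_block_graph(seed=seed)
        labels = pm.detect_communities(graph, seed=seed)
        assert pm.nmi(labels.labels, truth) >= 0.95

    def test_agrees_with_igraph_infomap(self):
        """Independent cross-check against igraph's flow-based detector."""
        pytest.importorskip("igraph")
        graph, truth = planted_block_graph(seed=7)
        ours = pm.detect_communities(graph, backend="greedy-mapeq", seed=1)
        theirs = pm.detect_communities(graph, backend="igraph-infomap", seed=1)
        assert pm.nmi(ours.labels, theirs.labels) >= 0.95

    def test_isolated_nodes_unassigned(self):
        graph = pm.TieDensityGraph(5, np.array([0, 1]), np.array([1, 2]),
                                   np.ones(2), 0.1, 0)
        labels = pm.detect_communities(graph, seed=0)
        assert labels.labels[3] == 0 and labels.labels[4] == 0

    def test_unknown_backend_lists_available(self):
        graph, _ = planted_block_graph()
        with pytest.raises(ValueError, match="greedy-mapeq"):
            pm.detect_communities(graph, backend="nope")


class TestSizeFilter:
    def _map(self, sizes):
        labels = np.concatenate(
            [np.full(s, lab) for lab, s in enumerate(sizes, start=1)]
        )
        table = LabelTable(tuple((i, f"community-{i}") for i in
                                 range(1, len(sizes) + 1)))
        return LabelMap(labels, table)

    def test_below_threshold_removed_at_boundary(self):
        m = self._map([399, 450])
        out = pm.size_filter(m, 400)
        assert (out.labels[:399] == 0).all()
        assert (out.labels[399:] == 2).all()

    def test_exactly_at_threshold_kept(self):
        m = self._map([400, 450])
        out = pm.size_filter(m, 400)
        assert (out.labels[:400] == 1).all()

    def test_all_large_is_identity(self):
        m = self._map([500, 600])
        assert pm.size_filter(m, 400) == m


class TestConsensusAcrossDensities:
    def _map(self, labels, n_labels):
        table = LabelTable(tuple((i, f"community-{i}") for i in
                                 range(1, n_labels + 1)))
        return LabelMap(np.array(labels), table)

    def test_single_map_identity(self):
        m = self._map([1, 1, 2, 2, 0, 0], 2)
        out = pm.consensus_across_densities([m])
        assert np.array_equal(out.labels, m.labels)

    def test_stringent_assignment_is_final(self):
        a = self._map([1, 1, 0, 0, 0, 0], 1)
        b = self._map([2, 2, 2, 2, 0, 0], 2)  # overlaps a -> harmonized to 1
        out = pm.consensus_across_densities([a, b])
        assert out.labels[0] == 1 and out.labels[1] == 1
        assert out.labels[2] == 1 and out.labels[3] == 1  # filled by matching

    def test_staggered_first_assigned_wins_bruteforce(self):
        """3 maps with staggered unassignment vs. literal first-wins rule,
        using identical label vocabularies so no harmonization is needed."""
        maps = [
            self._map([1, 0, 0, 2, 0, 0], 2),
            self._map([1, 1, 0, 2, 2, 0], 2),
            self._map([1, 1, 1, 2, 2, 2], 2),
        ]
        out = pm.consensus_across_densities(maps)
        stacked = np.array([m.labels for m in maps])
        expected = [next((v for v in col if v != 0), 0) for col in stacked.T]
        assert out.labels.tolist() == expected

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            pm.consensus_across_densities([])


class TestEnforceMinRegion:
    def test_small_island_absorbed(self, grid100):
        labels = np.ones(100, dtype=int)
        labels[0] = 2  # 1-node island of network 2 inside network 1
        table = LabelTable(((1, "community-1"), (2, "community-2")))
        out = pm.enforce_min_region(LabelMap(labels, table), grid100, 30)
        assert (out.labels == 1).all()

    def test_cluster_at_threshold_kept(self, grid100):
        labels = np.ones(100, dtype=int)
        labels[:30] = 2  # rows 0-2 of the 10x10 grid: contiguous, exactly 30
        table = LabelTable(((1, "community-1"), (2, "community-2")))
        out = pm.enforce_min_region(LabelMap(labels, table), grid100, 30)
        assert (out.labels[:30] == 2).all()

    def test_cascading_removal_reaches_fixed_point(self, grid100):
        """Absorbing one small cluster can leave another still small; the
        result must match brute-force iteration to convergence."""
        labels = np.ones(100, dtype=int)
        labels[:10] = 2    # row 0: 10 nodes of label 2
        labels[10:20] = 3  # row 1: 10 nodes of label 3
        table = LabelTable(
            ((1, "community-1"), (2, "community-2"), (3, "community-3"))
        )
        out = pm.enforce_min_region(LabelMap(labels, table), grid100, 25)
        # row 0 (size 10) joins row 1's label; the merged 20-node cluster is
        # still sub-threshold and must then be absorbed by the large network
        final = out.labels
        for lab in np.unique(final):
            assert (final == lab).sum() >= 25
        assert (final == 1).all()


class TestRelabelByJaccard:
    def test_identical_partition_full_match(self, grid100):
        ref = pm.plant_group_parcellation(grid100, 4, seed=0)
        anon_table = LabelTable(tuple((i, f"community-{i}") for i in (1, 2, 3, 4)))
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        anon = LabelMap(np.array([perm[v] for v in ref.labels]), anon_table)
        out = pm.relabel_by_jaccard(anon, ref, 0.2)
        assert np.array_equal(out.labels, ref.labels)

    def test_quarter_overlap_matched_at_threshold(self):
        # |A∩B| = 5, |A∪B| = 20 -> J = 0.25 >= 0.2
        anon = np.zeros(30, dtype=int); anon[0:15] = 1
        ref = np.zeros(30, dtype=int); ref[10:20] = 1
        anon_m = LabelMap(anon, LabelTable(((1, "community-1"),)))
        ref_m = LabelMap(ref, LabelTable(((1, "AUD"),)))
        out = pm.relabel_by_jaccard(anon_m, ref_m, 0.2)
        assert (out.labels[0:15] == 1).all()

    def test_below_threshold_unassigned(self):
        rng = np.random.default_rng(0)
        anon = np.zeros(200, dtype=int); anon[:100] = 1
        ref = np.zeros(200, dtype=int); ref[81:181] = 1  # J = 19/181 < 0.2
        anon_m = LabelMap(anon, LabelTable(((1, "community-1"),)))
        ref_m = LabelMap(ref, LabelTable(((1, "AUD"),)))
        out = pm.relabel_by_jaccard(anon_m, ref_m, 0.2)
        assert (out.labels == 0).all()
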