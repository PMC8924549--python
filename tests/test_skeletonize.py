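import numpy as np
import pytest
from scipy import sparse

from neuroskel.errors import EmptyObjectError
from neuroskel.skeleton import Skeleton
from neuroskel.skeletonize import (SkeletonizeParams, VoxelGraph,
                                   build_voxel_graph, find_seed,
                                   reconnect_components, shortest_paths,
                                   trace_skeleton)
from neuroskel.postprocess import PostprocessParams, postprocess
from neuroskel.volume import PointCloud, compute_dbf, pack_mask, SegmentationChunk
from neuroskel import synthetic

PP = PostprocessParams(resample_spacing_nm=3.0)


def _cloud(points, dbf, spacing=(1.0, 1.0, 1.0)):
    return PointCloud(np.asarray(points), spacing, np.asarray(dbf, dtype=float))


def _phantom_cloud(ph):
    return compute_dbf(pack_mask(ph.chunk, 1))


class TestVoxelGraph:
    def test_axis_neighbors_at_dbf_max_cost_step_only(self):
        g = build_voxel_graph(_cloud([[0, 0, 0], [1, 0, 0]], [2.0, 2.0]))
        assert g.costs[0, 1] == pytest.approx(1.0)
        assert g.costs[1, 0] == pytest.approx(1.0)

    def test_diagonal_step_is_sqrt3(self):
        g = build_voxel_graph(_cloud([[0, 0, 0], [1, 1, 1]], [2.0, 2.0]))
        assert g.costs[0, 1] == pytest.approx(np.sqrt(3))

    def test_penalty_added_toward_boundary_point(self):
        p = SkeletonizeParams(penalty_scale_nm=100.0, penalty_exponent=2.0)
        g = build_voxel_graph(_cloud([[0, 0, 0], [1, 0, 0]], [4.0, 2.0]), p)
        assert g.costs[1, 0] == pytest.approx(1.0)          # toward the center
        assert g.costs[0, 1] == pytest.approx(1.0 + 100 * 0.25)  # toward boundary

    def test_edge_set_matches_quadratic_scan(self):
        rng = np.random.default_rng(0)
        pts = np.argwhere(rng.random((6, 6, 6)) < 0.4)
        cloud = _cloud(pts, np.ones(len(pts)))
        g = build_voxel_graph(cloud)
        oracle = set()
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                if np.all(np.abs(pts[a] - pts[b]) <= 1):
                    oracle.add((a, b))
        assert g.edge_set() == oracle


class TestFindSeed:
    def test_argmax_of_dbf(self):
        assert find_seed(_cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [1.0, 5.0, 3.0])) == 1

    def test_tie_goes_to_lexicographically_first(self):
        assert find_seed(_cloud([[0, 0, 0], [1, 0, 0]], [2.0, 2.0])) == 0

    def test_empty_cloud_rejected(self):
        with pytest.raises(EmptyObjectError):
            find_seed(PointCloud(np.zeros((0, 3)), (1, 1, 1), np.zeros(0)))

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            dbf = rng.random(n)
            cloud = _cloud(np.arange(3 * n).reshape(n, 3), dbf)
            assert find_seed(cloud) == int(np.argmax(dbf))


def _bellman_ford(w, source):
    n = w.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    rows, cols = w.nonzero()
    for _ in range(n):
        changed = False
        for u, v in zip(rows, cols):
            if dist[u] + w[u, v] < dist[v] - 1e-15:
                dist[v] = dist[u] + w[u, v]
                changed = True
        if not changed:
            break
    return dist


def _graph_from_matrix(w):
    cloud = PointCloud(np.arange(3 * w.shape[0]).reshape(-1, 3), (1, 1, 1),
                       np.ones(w.shape[0]))
    return VoxelGraph(cloud, sparse.csr_matrix(w), cloud.positions_nm)


class TestShortestPaths:
    def test_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 2.0
        dist, pred = shortest_paths(_graph_from_matrix(w), 0)
        assert dist[2] == pytest.approx(3.0)
        assert pred[2] == 1 and pred[1] == 0

    def test_triangle_detour_wins(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 3.0
        dist, _ = shortest_paths(_graph_from_matrix(w), 0)
        assert dist[2] == pytest.approx(2.0)

    def test_source_out_of_range(self):
        with pytest.raises(IndexError):
            shortest_paths(_graph_from_matrix(np.zeros((2, 2))), 5)

    def test_unreachable_is_infinite(self):
        dist, _ = shortest_paths(_graph_from_matrix(np.zeros((2, 2))), 0)
        assert np.isinf(dist[1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bellman_ford(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        w = np.where(rng.random((n, n)) < 0.15, rng.uniform(0.1, 10, (n, n)), 0.0)
        w = np.triu(w, 1)
        w = w + w.T
        dist, _ = shortest_paths(_graph_from_matrix(w), 0)
        assert np.allclose(dist, _bellman_ford(w, 0), equal_nan=True)


def _endpoint_count(skel):
    """Terminals plus a root that is itself a path end (<= 1 child)."""
    _, n_children = skel.node_degree_classes()
    n = len(skel.terminal_rows())
    for r in skel.root_rows:
        if n_children[r] <= 1:
            n += 1
    return n


class TestTraceSkeleton:
    def test_cylinder_geometry(self):
        ph = synthetic.make_cylinder(100, 4)
        skel = postprocess(trace_skeleton(_phantom_cloud(ph)), PP)
        assert skel.n_trees == 1
        assert len(skel.branching_rows()) == 0
        p0, p1 = ph.truth_centerlines[0]
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        v = skel.xyz_nm - p0
        dev = np.linalg.norm(v - np.outer(v @ axis, axis), axis=1)
        assert dev.mean() <= np.sqrt(3)
        assert skel.total_path_length_nm() == pytest.approx(ph.truth_length_nm, rel=0.10)

    def test_y_phantom_single_branch_point(self):
        ph = synthetic.make_y(90)
        skel = postprocess(trace_skeleton(_phantom_cloud(ph)), PP)
        assert len(skel.branching_rows()) == ph.truth_topology["n_branching"]
        assert _endpoint_count(skel) == ph.truth_topology["n_terminals"]

    def test_single_voxel_cloud(self):
        chunk = SegmentationChunk(np.ones((1, 1, 1), dtype=np.uint32), (5, 5, 45))
        skel = trace_skeleton(compute_dbf(pack_mask(chunk, 1)))
        assert skel.n_nodes == 1
        assert skel.parent_ids[0] == -1
        assert skel.radius_nm[0] == pytest.approx(5.0)

    def test_nodes_lie_in_cloud_with_dbf_radius(self):
        ph = synthetic.make_y(90)
        cloud = _phantom_cloud(ph)
        skel = trace_skeleton(cloud)
        lut = {tuple(p): d for p, d in zip(cloud.positions_nm, cloud.dbf_nm)}
        for pos, r in zip(skel.xyz_nm, skel.radius_nm):
            assert lut[tuple(pos)] == pytest.approx(r)

    def test_deterministic(self):
        ph = synthetic.make_star(5)
        cloud = _phantom_cloud(ph)
        a = trace_skeleton(cloud)
        b = trace_skeleton(cloud)
        assert np.array_equal(a.xyz_nm, b.xyz_nm)
        assert np.array_equal(a.parent_ids, b.parent_ids)
        assert np.array_equal(a.radius_nm, b.radius_nm)

    def test_empty_cloud_rejected(self):
        with pytest.raises(EmptyObjectError):
            trace_skeleton(PointCloud(np.zeros((0, 3)), (1, 1, 1), np.zeros(0)))


def _chain(x0, x1, n, y=0.0):
    xyz = np.column_stack([np.linspace(x0, x1, n), np.full(n, y), np.zeros(n)])
    return xyz


def _forest(chains):
    xyz = np.concatenate(chains)
    parents = []
    base = 0
    for c in chains:
        parents.extend([-1] + list(range(base, base + len(c) - 1)))
        base += len(c)
    return Skeleton.from_arrays(xyz, np.ones(len(xyz)), np.asarray(parents))


class TestReconnect:
    def test_gap_within_threshold_joins(self):
        skel = _forest([_chain(0, 10, 5), _chain(20, 30, 5)])
        out = reconnect_components(skel, 20.0)
        assert out.n_trees == 1

    def test_gap_beyond_threshold_stays_split(self):
        skel = _forest([_chain(0, 10, 5), _chain(40, 50, 5)])
        out = reconnect_components(skel, 20.0)
        assert out.n_trees == 2

    def test_three_fragments_join_ascending_by_gap(self):
        # gaps: A-B = 5, B-C = 8, A-C = 28
        skel = _forest([_chain(0, 10, 5), _chain(15, 25, 5), _chain(33, 43, 5)])
        out = reconnect_components(skel, 10.0)
        assert out.n_trees == 1
        # the A-C bridge (28) must never be used: every edge is short
        assert out.edge_lengths_nm().max() <= 8.0 + 1e-9

    def test_connected_input_untouched(self):
        skel = _forest([_chain(0, 10, 5)])
        out = reconnect_components(skel, 1e9)
        assert out.n_trees == 1
        assert out.n_nodes == skel.n_nodes

    def test_total_node_count_preserved(self):
        skel = _forest([_chain(0, 10, 3), _chain(12, 20, 3), _chain(50, 60, 3)])
        out = reconnect_components(skel, 5.0)
        assert out.n_nodes == skel.n_nodes


def test_broken_tube_reconnects_iff_gap_within_threshold():
    ph = synthetic.make_broken_tube(gap_nm=10.0)
    skel = trace_skeleton(_phantom_cloud(ph))
    assert skel.n_trees == 2
    assert reconnect_components(skel, 20.0).n_trees == 1
    assert reconnect_components(skel, 5.0).n_trees == 2
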