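import numpy as np
import pytest

from neuroskel.skeleton import Skeleton
from neuroskel.postprocess import (PostprocessParams, postprocess,
                                   remove_empty_branches, remove_hair,
                                   remove_redundant_nodes,
                                   remove_soma_branches, resample, smooth)


def _skel(xyz, parents, radius=None):
    xyz = np.asarray(xyz, dtype=float)
    r = np.ones(len(xyz)) if radius is None else np.asarray(radius, dtype=float)
    return Skeleton.from_arrays(xyz, r, np.asarray(parents))


def _assert_valid_forest(skel):
    assert len(np.unique(skel.ids)) == skel.n_nodes
    assert len(skel.topological_order()) == skel.n_nodes  # acyclic, resolvable


class TestRedundantNodes:
    def test_duplicate_node_removed_child_reparented(self):
        s = _skel([[0, 0, 0], [5, 0, 0], [5, 0, 0], [10, 0, 0]], [-1, 0, 1, 2])
        out = remove_redundant_nodes(s, 1.0)
        assert out.n_nodes == 3
        _assert_valid_forest(out)

    def test_wide_gaps_unchanged(self):
        s = _skel([[0, 0, 0], [5, 0, 0], [10, 0, 0]], [-1, 0, 1])
        assert remove_redundant_nodes(s, 1.0).n_nodes == 3

    def test_keeps_larger_radius_of_merged_pair(self):
        s = _skel([[0, 0, 0], [5, 0, 0], [5.1, 0, 0], [10, 0, 0]],
                  [-1, 0, 1, 2], radius=[1, 1, 9, 1])
        out = remove_redundant_nodes(s, 0.5)
        assert 9.0 in out.radius_nm

    def test_matches_greedy_merge_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 30))
            gaps = rng.uniform(0, 2, n - 1)
            xs = np.concatenate([[0], np.cumsum(gaps)])
            s = _skel(np.column_stack([xs, np.zeros(n), np.zeros(n)]),
                      np.arange(-1, n - 1))
            out = remove_redundant_nodes(s, 1.0)
            # oracle: greedy forward scan; the two endpoints are irreducible
            kept, last, last_interior = 2, xs[0], False
            for x in xs[1:-1]:
                if x - last >= 1.0:
                    kept += 1
                    last = x
                    last_interior = True
            if last_interior and xs[-1] - last < 1.0:
                kept -= 1  # final interior node merges into the endpoint
            assert out.n_nodes == kept

    def test_idempotent(self):
        s = _skel([[0, 0, 0], [0.2, 0, 0], [5, 0, 0]], [-1, 0, 1])
        once = remove_redundant_nodes(s, 1.0)
        twice = remove_redundant_nodes(once, 1.0)
        assert np.array_equal(once.xyz_nm, twice.xyz_nm)


class TestHair:
    def _y_with_stub(self, stub_len, node_radius=50.0):
        # root - branching node (radius 50) - long limb + short stub
        xyz = [[0, 0, 0], [200, 0, 0], [400, 0, 0], [200, stub_len, 0]]
        return _skel(xyz, [-1, 0, 1, 1], radius=[1, node_radius, 1, 1])

    def test_short_terminal_stub_removed(self):
        out = remove_hair(self._y_with_stub(20.0), 1.5)  # 20 < 1.5 * 100
        assert out.n_nodes == 3
        assert len(out.branching_rows()) == 0

    def test_long_terminal_kept(self):
        out = remove_hair(self._y_with_stub(200.0), 1.5)
        assert out.n_nodes == 4

    def test_unbranched_path_unchanged(self, straight_skeleton):
        out = remove_hair(straight_skeleton, 1.5)
        assert out.n_nodes == straight_skeleton.n_nodes

    def test_iterates_to_fixpoint(self):
        # two nested stubs: removing the outer one exposes the inner one
        xyz = [[0, 0, 0], [200, 0, 0], [400, 0, 0],
               [200, 30, 0], [200, 60, 0], [230, 30, 0]]
        s = _skel(xyz, [-1, 0, 1, 1, 3, 3], radius=[1, 50, 1, 40, 1, 1])
        out = remove_hair(s, 1.5)
        assert len(out.branching_rows()) == 0


class TestSomaBranches:
    def test_stub_inside_root_sphere_removed(self):
        s = _skel([[0, 0, 0], [10, 0, 0], [0, 30, 0], [0, 200, 0]],
                  [-1, 0, 0, 2], radius=[100, 1, 1, 1])
        out = remove_soma_branches(s)
        assert out.n_nodes == 3  # the 10 nm stub went; the exiting limb stayed

    def test_limb_exiting_sphere_kept(self):
        s = _skel([[0, 0, 0], [50, 0, 0], [300, 0, 0]], [-1, 0, 1],
                  radius=[100, 1, 1])
        assert remove_soma_branches(s).n_nodes == 3

    def test_zero_radius_root_unchanged(self):
        s = _skel([[0, 0, 0], [1, 0, 0]], [-1, 0], radius=[0, 1])
        assert remove_soma_branches(s).n_nodes == 2


class TestResample:
    def test_uniform_spacing_node_count(self, straight_skeleton):
        out = resample(straight_skeleton, 10.0)
        assert out.n_nodes == 11

    def test_coarse_spacing_keeps_endpoints(self, straight_skeleton):
        out = resample(straight_skeleton, 1000.0)
        assert out.n_nodes == 2
        xs = np.sort(out.xyz_nm[:, 0])
        assert xs[0] == pytest.approx(0.0) and xs[-1] == pytest.approx(100.0)

    def test_straight_path_length_preserved(self, straight_skeleton):
        out = resample(straight_skeleton, 7.0)
        assert out.total_path_length_nm() == pytest.approx(100.0)

    def test_irreducible_positions_exact(self, y_skeleton):
        out = resample(y_skeleton, 3.0)
        for r in y_skeleton.irreducible_rows():
            assert np.any(np.all(np.isclose(out.xyz_nm, y_skeleton.xyz_nm[r]), axis=1))

    def test_radii_interpolated(self):
        s = _skel([[0, 0, 0], [100, 0, 0]], [-1, 0], radius=[0.0, 10.0])
        out = resample(s, 50.0)
        mid = np.argmin(np.abs(out.xyz_nm[:, 0] - 50.0))
        assert out.radius_nm[mid] == pytest.approx(5.0)

    def test_idempotent(self, straight_skeleton):
        once = resample(straight_skeleton, 7.0)
        twice = resample(once, 7.0)
        assert once.n_nodes == twice.n_nodes
        assert np.allclose(np.sort(once.xyz_nm[:, 0]), np.sort(twice.xyz_nm[:, 0]))


class TestEmptyBranches:
    def test_zero_length_terminal_removed(self):
        s = _skel([[0, 0, 0], [10, 0, 0], [20, 0, 0], [10, 0, 0]], [-1, 0, 1, 1])
        out = remove_empty_branches(s)
        assert out.n_nodes == 3

    def test_normal_y_unchanged(self, y_skeleton):
        assert remove_empty_branches(y_skeleton).n_nodes == 4

    def test_idempotent(self, y_skeleton):
        once = remove_empty_branches(y_skeleton)
        assert remove_empty_branches(once).n_nodes == once.n_nodes


class TestSmooth:
    def test_collinear_fixed_point(self, straight_skeleton):
        out = smooth(straight_skeleton, 3)
        assert np.allclose(out.xyz_nm, straight_skeleton.xyz_nm, atol=1e-9)

    def test_zigzag_average(self):
        xs = [0, 0, 1, 0, 0]
        s = _skel(np.column_stack([np.arange(5) * 10.0, xs, np.zeros(5)]),
                  np.arange(-1, 4))
        out = smooth(s, 3)
        assert out.xyz_nm[2, 1] == pytest.approx(1 / 3)

    def test_endpoints_fixed(self):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(0, 100, (8, 3))
        s = Skeleton.from_arrays(xyz, np.ones(8), np.arange(-1, 7))
        out = smooth(s, 5)
        assert np.allclose(out.xyz_nm[0], xyz[0])
        assert np.allclose(out.xyz_nm[-1], xyz[-1])

    def test_even_window_rejected(self, straight_skeleton):
        with pytest.raises(ValueError):
            smooth(straight_skeleton, 4)


def test_full_pipeline_preserves_extremal_nodes_and_validity():
    from neuroskel import synthetic, pack_mask, compute_dbf, trace_skeleton
    ph = synthetic.make_cylinder(100, 4)
    raw = trace_skeleton(compute_dbf(pack_mask(ph.chunk, 1)))
    out = postprocess(raw, PostprocessParams(resample_spacing_nm=3.0))
    _assert_valid_forest(out)
    # path extremes survive the cleanup: extent along the axis is preserved
    assert np.ptp(out.xyz_nm[:, 0]) == pytest.approx(np.ptp(raw.xyz_nm[:, 0]), abs=3.0)
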