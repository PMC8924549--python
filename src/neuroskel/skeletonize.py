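"""Modified-TEASAR centerline tracing over a foreground point cloud.

The tracer follows the classic sparse-skeletonization loop:

1. build a 26-connectivity graph over the foreground voxels, with edge costs
   equal to the physical step length plus a center-hugging penalty that grows
   as the head voxel's distance-from-boundary (DBF) shrinks;
2. seed at the point of maximal DBF;
3. repeatedly run Dijkstra from the current seed, take the farthest (by graph
   distance) unvisited point as the destination, extract the shortest path
   and append it to the skeleton, attaching at the first already-skeletonized
   node encountered from the destination side;
4. invalidate (mark visited) every point within a DBF-scaled radius of each
   new path node;
5. once a path exists, each further iteration re-seeds at the unvisited point
   closest to the visited set, and stops when every point is visited.

One tree is produced per connected component of the voxel graph; fragments
produced by discontinuous segmentation can afterwards be re-joined with
:func:`reconnect_components` at their nearest terminal nodes within a
distance threshold.  The whole loop is deterministic: ties are broken by
lexicographic voxel order and no RNG is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .errors import EmptyObjectError
from .skeleton import Skeleton
from .volume import PointCloud

__all__ = [
    "SkeletonizeParams", "VoxelGraph",
    "build_voxel_graph", "find_seed", "shortest_paths",
    "trace_skeleton", "reconnect_components",
]

# the 26-neighborhood, split into 13 half-space offsets (their negatives
# complete the stencil)
_HALF_OFFSETS = np.array([(di, dj, dk)
                          for di in (-1, 0, 1)
                          for dj in (-1, 0, 1)
                          for dk in (-1, 0, 1)
                          if (di, dj, dk) > (0, 0, 0)], dtype=np.int64)


@dataclass
class SkeletonizeParams:
    """Tunable parameters of the tracer.

    penalty_scale_nm : weight of the center-hugging penalty added to each
        graph edge; the penalty is ``scale * (1 - dbf/dbf_max)**exponent``
        evaluated at the edge's head node, so steps toward the boundary are
        expensive and the path hugs the object center.
    penalty_exponent : sharpness of the penalty (>= 1).
    invalidation_scale : visited-ball radius per path node, in units of that
        node's DBF.
    invalidation_min_nm : floor on the visited-ball radius; defaults to twice
        the smallest voxel spacing when left at None.
    reconnect_threshold_nm : maximal terminal-to-terminal gap that
        :func:`reconnect_components` will bridge.
    """

    penalty_scale_nm: float = 5000.0
    penalty_exponent: float = 16.0
    invalidation_scale: float = 3.0
    invalidation_min_nm: float | None = None
    reconnect_threshold_nm: float = 5000.0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.penalty_scale_nm, self.invalidation_scale,
               self.reconnect_threshold_nm) <= 0:
            raise ValueError("parameters must be positive")
        if self.penalty_exponent < 1:
            raise ValueError("penalty_exponent must be >= 1")
        if self.invalidation_min_nm is not None and self.invalidation_min_nm <= 0:
            raise ValueError("invalidation_min_nm must be positive")

    def resolved_invalidation_min(self, spacing_nm) -> float:
        if self.invalidation_min_nm is not None:
            return float(self.invalidation_min_nm)
        return 2.0 * float(min(spacing_nm))


@dataclass
class VoxelGraph:
    """26-connectivity graph over a point cloud.

    ``costs`` is a directed CSR matrix: the cost of u->v is the physical step
    length plus the penalty at v, so the matrix is structurally symmetric but
    the two directions of an edge may differ in weight.
    """

    cloud: PointCloud
    costs: sparse.csr_matrix
    positions_nm: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cloud)

    def edge_set(self):
        """Set of undirected (u, v) index pairs, u < v."""
        coo = self.costs.tocoo()
        return {(min(int(u), int(v)), max(int(u), int(v)))
                for u, v in zip(coo.row, coo.col)}


def build_voxel_graph(cloud: PointCloud, params: SkeletonizeParams | None = None) -> VoxelGraph:
    """Connect 26-adjacent points; edge cost = step length + DBF penalty."""
    if len(cloud) == 0 or cloud.dbf_nm is None:
        raise EmptyObjectError("need a nonempty point cloud with dbf set")
    params = params or SkeletonizeParams()
    pts = cloud.points_vox
    spacing = np.asarray(cloud.spacing_nm)
    dbf = cloud.dbf_nm
    dbf_max = dbf.max()
    penalty = params.penalty_scale_nm * (1.0 - dbf / dbf_max) ** params.penalty_exponent

    # dense index grid over the bounding box for O(1) neighbor lookup
    lo = pts.min(axis=0)
    shape = pts.max(axis=0) - lo + 1
    grid = np.full(shape, -1, dtype=np.int64)
    rel = pts - lo
    grid[tuple(rel.T)] = np.arange(len(pts))

    rows, cols, data = [], [], []
    for off in _HALF_OFFSETS:
        nb = rel + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        u = np.flatnonzero(ok)
        v = grid[tuple(nb[ok].T)]
        hit = v >= 0
        u, v = u[hit], v[hit]
        if len(u) == 0:
            continue
        step = float(np.linalg.norm(off * spacing))
        rows.extend((u, v))
        cols.extend((v, u))
        data.extend((step + penalty[v], step + penalty[u]))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
    costs = sparse.csr_matrix((data, (rows, cols)), shape=(len(pts), len(pts)))
    return VoxelGraph(cloud, costs, cloud.positions_nm)


def find_seed(cloud: PointCloud) -> int:
    """Index of the point with the largest DBF; ties go to the point that is
    lexicographically first (the cloud is stored in lexicographic order)."""
    if len(cloud) == 0:
        raise EmptyObjectError("empty point cloud")
    return int(np.argmax(cloud.dbf_nm))


def shortest_paths(graph: VoxelGraph, source: int):
    """Single-source Dijkstra; returns (distances, predecessors).

    Unreachable nodes get infinite distance and predecessor -9999 (scipy's
    sentinel)."""
    if not (0 <= source < graph.n_nodes):
        raise IndexError(f"source {source} out of range")
    dist, pred = csgraph.dijkstra(graph.costs, directed=True, indices=source,
                                  return_predecessors=True)
    return dist, pred


def _walk_path(pred: np.ndarray, dest: int) -> list:
    """Predecessor chain from dest back to the Dijkstra source, dest-first."""
    path = [int(dest)]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return path


def trace_skeleton(cloud: PointCloud, params: SkeletonizeParams | None = None) -> Skeleton:
    """Trace the centerline skeleton of one object's point cloud.

    Returns a forest with one tree per connected component; each tree is
    rooted at its node of maximal radius (a soma proxy).  Node radii are the
    DBF values of the underlying voxels.
    """
    if len(cloud) == 0:
        raise EmptyObjectError("empty point cloud")
    params = params or SkeletonizeParams()
    graph = build_voxel_graph(cloud, params)
    n = graph.n_nodes
    pos = graph.positions_nm
    dbf = cloud.dbf_nm
    r_min = params.resolved_invalidation_min(cloud.spacing_nm)
    kdtree = cKDTree(pos)

    n_comp, comp = csgraph.connected_components(graph.costs, directed=False)
    visited = np.zeros(n, dtype=bool)
    node_of_point = np.full(n, -1, dtype=np.int64)  # point idx -> skeleton row

    sk_xyz, sk_radius, sk_parent, sk_point = [], [], [], []

    def add_node(point_idx: int, parent_row: int) -> int:
        row = len(sk_xyz)
        sk_xyz.append(pos[point_idx])
        sk_radius.append(dbf[point_idx])
        sk_parent.append(parent_row)
        sk_point.append(point_idx)
        node_of_point[point_idx] = row
        return row

    def invalidate(path_points):
        for p in path_points:
            r = max(params.invalidation_scale * dbf[p], r_min)
            visited[np.asarray(kdtree.query_ball_point(pos[p], r), dtype=np.int64)] = True
        visited[np.asarray(path_points, dtype=np.int64)] = True

    for c in range(n_comp):
        comp_mask = comp == c
        comp_has_skeleton = False
        while True:
            unvisited = np.flatnonzero(comp_mask & ~visited)
            if len(unvisited) == 0:
                break
            if not comp_has_skeleton:
                # initial seed: global DBF maximum of the component
                seed = int(unvisited[np.argmax(dbf[unvisited])])
            else:
                # re-seed at the unvisited point closest to the visited set
                vis_idx = np.flatnonzero(comp_mask & visited)
                vtree = cKDTree(pos[vis_idx])
                d, _ = vtree.query(pos[unvisited])
                seed = int(unvisited[np.argmin(d)])
            dist, pred = shortest_paths(graph, seed)
            reach = unvisited[np.isfinite(dist[unvisited])]
            dest = int(reach[np.argmax(dist[reach])])
            # walk dest -> seed; stop early at the first already-skeletonized
            # point (that node becomes the attachment)
            chain = []
            touched_skeleton = False
            for p in _walk_path(pred, dest):
                chain.append(p)
                if node_of_point[p] >= 0:
                    touched_skeleton = True
                    break
            chain.reverse()  # proximal -> distal
            if not touched_skeleton and comp_has_skeleton:
                # the dest path never touched the skeleton: prepend the graph
                # shortest path from the seed to the nearest (by graph
                # distance) skeleton point, so the junction follows the
                # centerline instead of jumping straight across space
                sk_pts = np.flatnonzero(node_of_point >= 0)
                sk_pts = sk_pts[np.isfinite(dist[sk_pts])]
                if len(sk_pts):
                    near = int(sk_pts[np.argmin(dist[sk_pts])])
                    connector = _walk_path(pred, near)  # [near, ..., seed]
                    # [near, ..., seed] + [seed, ..., dest] minus repeated seed
                    chain = connector + chain[1:]
            parent = -1
            new_pts = []
            for p in chain:
                existing = int(node_of_point[p])
                if existing >= 0:
                    parent = existing  # shared prefix / attachment node
                    continue
                parent = add_node(p, parent)
                new_pts.append(p)
            invalidate(new_pts if new_pts else [dest])
            comp_has_skeleton = True

    skel = Skeleton.from_arrays(np.asarray(sk_xyz), np.asarray(sk_radius),
                                np.asarray(sk_parent, dtype=np.int64))
    # root each tree at its maximal-radius node (soma proxy)
    return _reroot_at_max_radius(skel)


def _reroot_at_max_radius(skel: Skeleton) -> Skeleton:
    labels = skel.tree_labels()
    for t in range(skel.n_trees):
        rows = np.flatnonzero(labels == t)
        best = int(rows[np.argmax(skel.radius_nm[rows])])
        if skel.parent_ids[best] != -1:
            skel = skel.reroot(best)
            labels = skel.tree_labels()
    return skel


def reconnect_components(skel: Skeleton, threshold_nm: float) -> Skeleton:
    """Greedily bridge skeleton fragments at their nearest terminal-or-root
    node pairs, ascending by gap, while the smallest inter-tree gap is within
    ``threshold_nm``.  The absorbed tree is re-rooted at its joining node."""
    skel = skel.copy()
    while skel.n_trees >= 2:
        labels = skel.tree_labels()
        is_root, n_children = skel.node_degree_classes()
        candidate = np.flatnonzero(is_root | (n_children == 0))
        best = None  # (gap, row_a, row_b)
        for ia in range(len(candidate)):
            a = candidate[ia]
            for ib in range(ia + 1, len(candidate)):
                b = candidate[ib]
                if labels[a] == labels[b]:
                    continue
                gap = float(np.linalg.norm(skel.xyz_nm[a] - skel.xyz_nm[b]))
                if best is None or gap < best[0]:
                    best = (gap, int(a), int(b))
        if best is None or best[0] > threshold_nm:
            break
        _, a, b = best
        # absorb the smaller tree (tie: the later tree label) into the other
        na = int(np.sum(labels == labels[a]))
        nb = int(np.sum(labels == labels[b]))
        if (nb, labels[b]) <= (na, labels[a]):
            keep, absorb = a, b
        else:
            keep, absorb = b, a
        skel = skel.reroot(absorb)
        pr = skel.parent_rows
        pr[absorb] = keep
        skel = Skeleton.from_arrays(skel.xyz_nm, skel.radius_nm, pr, skel.structure)
    return skel
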