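"""Morphometrics: segment decomposition, per-segment and per-neuron features.

A skeleton decomposes into *segments*: maximal unbranched paths between
consecutive irreducible nodes (the root, branching nodes and terminals).
Per-segment features (branch order, path length, tortuosity, branching
angle, ...) support single-neuron analysis; per-neuron aggregates (total
path length, Sholl intersection profile, asymmetry, fractal dimension,
convex-hull volume, frustum surface area, synapse counts) form the feature
vector used to compare neurons across a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import UndefinedFeatureError
from .skeleton import Skeleton

__all__ = [
    "SegmentDecomposition", "decompose", "segment_features", "sholl",
    "neuron_features", "fractal_dimension", "hull_volume", "surface_area",
]


@dataclass
class SegmentDecomposition:
    """A skeleton cut into segments between irreducible nodes.

    ``segments[k]`` is the row-path of segment k (proximal irreducible node
    first); ``order[k]`` counts branch points passed from the root (the
    root-adjacent segment has order 0); ``is_terminal[k]`` marks segments
    ending at a terminal node.
    """

    skeleton: Skeleton
    segments: list
    order: np.ndarray
    is_terminal: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def decompose(skel: Skeleton) -> SegmentDecomposition:
    """Cut a single-tree skeleton at every irreducible node.

    Segment order increases by one each time a segment starts at a deeper
    irreducible node: root-adjacent segments have order 0.
    """
    if skel.n_trees != 1:
        raise ValueError("decompose needs a single tree; reconnect or split first")
    terminal = set(int(t) for t in skel.terminal_rows())
    segments = list(skel.iter_segments())
    # order: BFS over the segment graph from the root
    seg_order = np.zeros(len(segments), dtype=np.int64)
    start_of = {}
    for k, seg in enumerate(segments):
        start_of.setdefault(int(seg[0]), []).append(k)
    root = int(skel.root_rows[0])
    depth = {root: 0}
    stack = [root]
    order_map = {}
    while stack:
        node = stack.pop()
        for k in start_of.get(node, []):
            order_map[k] = depth[node]
            end = int(segments[k][-1])
            depth[end] = depth[node] + 1
            stack.append(end)
    for k in range(len(segments)):
        seg_order[k] = order_map[k]
    is_term = np.array([int(s[-1]) in terminal for s in segments], dtype=bool)
    return SegmentDecomposition(skel, segments, seg_order, is_term)


def _branching_angles(skel: Skeleton, decomp: SegmentDecomposition) -> dict:
    """Mean pairwise daughter-daughter angle per branching node.

    The direction of a daughter segment is the unit vector from the
    branching node toward that segment's distal irreducible node, which is
    robust to node jitter near the branch point.
    """
    daughters = {}
    for seg in decomp.segments:
        daughters.setdefault(int(seg[0]), []).append(int(seg[-1]))
    angles = {}
    for node, ends in daughters.items():
        if len(ends) < 2:
            continue
        dirs = []
        for e in ends:
            v = skel.xyz_nm[e] - skel.xyz_nm[node]
            n = np.linalg.norm(v)
            if n > 0:
                dirs.append(v / n)
        pair_angles = []
        for a in range(len(dirs)):
            for b in range(a + 1, len(dirs)):
                c = float(np.clip(np.dot(dirs[a], dirs[b]), -1.0, 1.0))
                pair_angles.append(np.arccos(c))
        if pair_angles:
            angles[node] = float(np.mean(pair_angles))
    return angles


def _dist_to_root(skel: Skeleton) -> np.ndarray:
    """Path length from every node to its tree's root."""
    pr = skel.parent_rows
    out = np.zeros(skel.n_nodes)
    for r in skel.topological_order():
        p = pr[r]
        if p >= 0:
            out[r] = out[p] + np.linalg.norm(skel.xyz_nm[r] - skel.xyz_nm[p])
    return out


def segment_features(decomp: SegmentDecomposition) -> pd.DataFrame:
    """One row per segment: order, path length, branching angle, tortuosity,
    path distance to root, mean radius, and the neck/head radius ratio of
    terminal segments (a spine signature).

    Tortuosity is path length over the chord between the segment's
    endpoints; it is NaN when the chord degenerates to zero.  The branching
    angle column holds the mean daughter-pair angle at the segment's
    proximal node (NaN for segments leaving a non-branching root).
    """
    skel = decomp.skeleton
    angles = _branching_angles(skel, decomp)
    d2r = _dist_to_root(skel)
    rows = []
    for k, seg in enumerate(decomp.segments):
        xyz = skel.xyz_nm[seg]
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        length = float(steps.sum())
        chord = float(np.linalg.norm(xyz[-1] - xyz[0]))
        tort = length / chord if chord > 0 else np.nan
        neck_head = np.nan
        if decomp.is_terminal[k]:
            neck_head = _neck_head_ratio(skel, seg)
        rows.append({
            "order": int(decomp.order[k]),
            "path_length_nm": length,
            "branching_angle_rad": angles.get(int(seg[0]), np.nan),
            "tortuosity": tort,
            "dist_to_root_nm": float(d2r[seg[0]]),
            "mean_radius_nm": float(skel.radius_nm[seg].mean()),
            "is_terminal": bool(decomp.is_terminal[k]),
            "neck_head_ratio": neck_head,
        })
    return pd.DataFrame(rows)


def _neck_head_ratio(skel: Skeleton, seg) -> float:
    """min radius in the proximal half / max radius in the distal half,
    split at the arc-length midpoint of a terminal segment."""
    xyz = skel.xyz_nm[seg]
    rad = skel.radius_nm[seg]
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))])
    if arc[-1] == 0:
        return np.nan
    half = arc[-1] / 2.0
    prox = rad[arc <= half]
    dist = rad[arc >= half]
    if len(prox) == 0 or len(dist) == 0 or dist.max() == 0:
        return np.nan
    return float(prox.min() / dist.max())


def sholl(skel: Skeleton, radii_nm) -> np.ndarray:
    """Sholl profile: intersections of the skeleton with concentric spheres
    centered on the root.

    An edge (a, b) crosses radius r when ``(|a-root| - r) * (|b-root| - r) < 0``;
    nodes lying exactly on a sphere count once each.
    """
    radii = np.asarray(radii_nm, dtype=np.float64)
    if len(radii) and (np.any(np.diff(radii) <= 0) or radii[0] <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    root = skel.root_rows[0]
    d = np.linalg.norm(skel.xyz_nm - skel.xyz_nm[root], axis=1)
    edges = skel.edge_rows()
    counts = np.zeros(len(radii), dtype=np.int64)
    for i, r in enumerate(radii):
        if len(edges):
            crossing = (d[edges[:, 0]] - r) * (d[edges[:, 1]] - r) < 0
            counts[i] = int(crossing.sum())
        counts[i] += int(np.sum(d == r))
    return counts


def fractal_dimension(points: np.ndarray) -> float:
    """Box-counting dimension of a point set.

    Boxes are dyadic: side s = extent/2, extent/4, ..., extent/64 where
    extent is the largest axis range; the dimension is the least-squares
    slope of log N(s) against log(1/s).  Requires >= 32 points and a
    non-degenerate extent.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 32:
        raise UndefinedFeatureError("fractal dimension needs >= 32 points")
    lo = points.min(axis=0)
    extent = float((points.max(axis=0) - lo).max())
    if extent <= 0:
        raise UndefinedFeatureError("degenerate extent")
    log_n, log_inv_s = [], []
    for k in range(1, 7):  # sizes extent/2 .. extent/64
        s = extent / 2 ** k
        idx = np.floor((points - lo) / s).astype(np.int64)
        idx = np.minimum(idx, 2 ** k - 1)  # points on the far face
        n = len(np.unique(idx, axis=0))
        log_n.append(np.log(n))
        log_inv_s.append(np.log(1.0 / s))
    slope, _ = np.polyfit(log_inv_s, log_n, 1)
    return float(slope)


def hull_volume(points: np.ndarray) -> float:
    """Convex hull volume in nm^3; 0 for degenerate (coplanar or < 4) sets."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 4:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def surface_area(skel: Skeleton) -> float:
    """Membrane surface proxy: sum of lateral frustum areas over all edges,
    ``pi * (r1 + r2) * slant`` with ``slant = sqrt(len^2 + (r1 - r2)^2)``."""
    edges = skel.edge_rows()
    if len(edges) == 0:
        return 0.0
    r1 = skel.radius_nm[edges[:, 0]]
    r2 = skel.radius_nm[edges[:, 1]]
    lengths = skel.edge_lengths_nm()
    slant = np.sqrt(lengths ** 2 + (r1 - r2) ** 2)
    return float(np.sum(np.pi * (r1 + r2) * slant))


def neuron_features(skel: Skeleton, synapses: pd.DataFrame | None = None,
                    neuron_id: int | None = None,
                    sholl_radii_nm=None) -> dict:
    """Whole-neuron feature vector as a plain dict.

    mass center = unweighted mean of node coordinates; asymmetry = distance
    from the root (soma) to the mass center; typical radius = RMS distance
    of nodes to the mass center.  Synapse counts are taken from ``synapses``
    (a table with presyn/postsyn columns) when given, else left as NaN.
    Fractal dimension is NaN when undefined for the node set.
    """
    decomp = decompose(skel)
    feats = segment_features(decomp)
    root = int(skel.root_rows[0])
    center = skel.xyz_nm.mean(axis=0)
    d_center = np.linalg.norm(skel.xyz_nm - center, axis=1)
    if sholl_radii_nm is None:
        rmax = float(np.linalg.norm(skel.xyz_nm - skel.xyz_nm[root], axis=1).max())
        sholl_radii_nm = np.linspace(rmax / 10, rmax, 10) if rmax > 0 else np.array([])
    try:
        fd = fractal_dimension(skel.xyz_nm)
    except UndefinedFeatureError:
        fd = np.nan
    n_post = n_pre = np.nan
    if synapses is not None and neuron_id is not None:
        n_pre = int((synapses["presyn"] == neuron_id).sum())
        n_post = int((synapses["postsyn"] == neuron_id).sum())
    return {
        "soma_to_mass_center_nm": float(np.linalg.norm(skel.xyz_nm[root] - center)),
        "total_path_length_nm": skel.total_path_length_nm(),
        "n_branching_points": int(len(skel.branching_rows())),
        "median_segment_length_nm": float(feats["path_length_nm"].median()) if len(feats) else 0.0,
        "sholl_counts": np.asarray(sholl(skel, sholl_radii_nm), dtype=np.int64),
        "mean_branching_rad": float(feats["branching_angle_rad"].mean()),
        "mean_tortuosity": float(feats["tortuosity"].mean()),
        "asymmetry_nm": float(np.linalg.norm(skel.xyz_nm[root] - center)),
        "typical_radius_nm": float(np.sqrt(np.mean(d_center ** 2))),
        "fractal_dimension": fd,
        "root_radius_nm": float(skel.radius_nm[root]),
        "longest_segment_nm": float(feats["path_length_nm"].max()) if len(feats) else 0.0,
        "hull_volume_nm3": hull_volume(skel.xyz_nm),
        "surface_area_nm2": surface_area(skel),
        "n_postsynapses": n_post,
        "n_presynapses": n_pre,
    }
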