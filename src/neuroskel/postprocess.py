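"""Skeleton cleanup: the six-step pipeline applied after tracing.

In order: redundant-node removal, hair removal (short terminal stubs judged
against the attachment diameter), removal of branches inside the cell body,
arc-length resampling, empty-branch removal, and coordinate smoothing.
Every step maps a forest to a forest and is idempotent on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import Skeleton

__all__ = [
    "PostprocessParams", "remove_redundant_nodes", "remove_hair",
    "remove_soma_branches", "resample", "remove_empty_branches", "smooth",
    "postprocess",
]


@dataclass
class PostprocessParams:
    """Cleanup knobs.

    hair_ratio : a terminal segment is "hair" when its path length is below
        ``hair_ratio * (2 * radius of its attachment branching node)``.
    resample_spacing_nm : target node spacing along each segment.
    smooth_window : odd moving-average window for coordinate smoothing.
    redundant_eps_nm : consecutive nodes closer than this are merged; when
        None, the smallest voxel spacing should be passed by the caller.
    """

    hair_ratio: float = 1.5
    resample_spacing_nm: float = 500.0
    smooth_window: int = 3
    redundant_eps_nm: float = 1.0

    def __post_init__(self):
        if min(self.hair_ratio, self.resample_spacing_nm, self.redundant_eps_nm) <= 0:
            raise ValueError("parameters must be positive")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")


def _path_length(skel: Skeleton, rows) -> float:
    xyz = skel.xyz_nm[rows]
    return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


def remove_redundant_nodes(skel: Skeleton, eps_nm: float) -> Skeleton:
    """Merge consecutive sub-``eps_nm`` nodes along each segment, keeping the
    larger-radius node of each merged run; irreducible nodes are never
    removed."""
    drop = np.zeros(skel.n_nodes, dtype=bool)
    for seg in skel.iter_segments():
        # greedy scan: interior nodes only (endpoints are irreducible)
        kept = seg[0]
        for r in seg[1:-1]:
            gap = np.linalg.norm(skel.xyz_nm[r] - skel.xyz_nm[kept])
            if gap < eps_nm:
                # merge the pair: keep whichever has the larger radius, but an
                # irreducible "kept" anchor always survives
                if kept == seg[0] or skel.radius_nm[kept] >= skel.radius_nm[r]:
                    drop[r] = True
                else:
                    drop[kept] = True
                    kept = r
            else:
                kept = r
        # last interior node vs distal endpoint
        if len(seg) > 2 and not drop[seg[-2]]:
            gap = np.linalg.norm(skel.xyz_nm[seg[-1]] - skel.xyz_nm[seg[-2]])
            if gap < eps_nm:
                drop[seg[-2]] = True
    if not drop.any():
        return skel.copy()
    return skel.keep_rows(~drop)


def remove_hair(skel: Skeleton, hair_ratio: float = 1.5) -> Skeleton:
    """Delete terminal segments shorter than ``hair_ratio`` times the
    diameter of their attachment branching node; iterate to fixpoint.  A
    segment whose proximal end is the root is exempt."""
    while True:
        branching = set(int(b) for b in skel.branching_rows())
        root_rows = set(int(r) for r in skel.root_rows)
        drop = np.zeros(skel.n_nodes, dtype=bool)
        terminal = set(int(t) for t in skel.terminal_rows())
        changed = False
        for seg in skel.iter_segments():
            prox, dist = int(seg[0]), int(seg[-1])
            if dist not in terminal or prox not in branching or prox in root_rows:
                continue
            length = _path_length(skel, seg)
            if length < hair_ratio * 2.0 * skel.radius_nm[prox]:
                drop[seg[1:]] = True
                changed = True
        if not changed:
            return skel.copy()
        skel = skel.keep_rows(~drop)


def remove_soma_branches(skel: Skeleton) -> Skeleton:
    """Delete every branch (subtree) all of whose nodes lie strictly inside
    the sphere centered at its tree's root with the root's radius.  Branches
    that exit the sphere are kept entirely."""
    labels = skel.tree_labels()
    roots = skel.root_rows
    inside = np.zeros(skel.n_nodes, dtype=bool)
    for t, root in enumerate(roots):
        rows = np.flatnonzero(labels == t)
        r = skel.radius_nm[root]
        if r <= 0:
            continue
        d = np.linalg.norm(skel.xyz_nm[rows] - skel.xyz_nm[root], axis=1)
        inside[rows[d < r]] = True
    inside[roots] = False  # the root itself always survives
    if not inside.any():
        return skel.copy()
    # a node is dropped iff its entire subtree is inside the sphere
    kids = skel.children_map()
    all_in = inside.copy()
    for r in skel.topological_order()[::-1]:
        for c in kids[r]:
            all_in[r] = all_in[r] and all_in[c]
    if not all_in.any():
        return skel.copy()
    return skel.keep_rows(~all_in)


def resample(skel: Skeleton, spacing_nm: float) -> Skeleton:
    """Re-parameterize each segment by arc length at uniform ``spacing_nm``.

    Irreducible node positions/radii are preserved exactly; interior node
    positions and radii are linearly interpolated along the old polyline.
    """
    if skel.n_nodes == 0:
        return skel.copy()
    irreducible = skel.irreducible_rows()
    # new node table: all irreducible nodes first, then fresh interior nodes
    new_xyz = [skel.xyz_nm[r] for r in irreducible]
    new_rad = [skel.radius_nm[r] for r in irreducible]
    new_struct = [skel.structure[r] for r in irreducible]
    new_parent = [-1] * len(irreducible)
    row_of = {int(r): i for i, r in enumerate(irreducible)}
    for seg in skel.iter_segments():
        xyz = skel.xyz_nm[seg]
        rad = skel.radius_nm[seg]
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xyz, axis=0), axis=1))])
        total = arc[-1]
        n_iv = max(1, int(np.ceil(total / spacing_nm - 1e-9))) if total > 0 else 1
        ts = np.linspace(0.0, total, n_iv + 1)[1:-1]
        parent = row_of[int(seg[0])]
        for t in ts:
            p = [np.interp(t, arc, xyz[:, d]) for d in range(3)]
            new_xyz.append(np.asarray(p))
            new_rad.append(np.interp(t, arc, rad))
            new_struct.append(skel.structure[seg[1]])
            new_parent.append(parent)
            parent = len(new_xyz) - 1
        new_parent[row_of[int(seg[-1])]] = parent
    return Skeleton.from_arrays(np.asarray(new_xyz), np.asarray(new_rad),
                                np.asarray(new_parent, dtype=np.int64),
                                np.asarray(new_struct, dtype=np.int32))


def remove_empty_branches(skel: Skeleton) -> Skeleton:
    """Delete zero-path-length terminal segments (a terminal child coincident
    with its branching node)."""
    drop = np.zeros(skel.n_nodes, dtype=bool)
    terminal = set(int(t) for t in skel.terminal_rows())
    for seg in skel.iter_segments():
        if int(seg[-1]) in terminal and _path_length(skel, seg) == 0.0:
            drop[seg[1:]] = True
    if not drop.any():
        return skel.copy()
    return skel.keep_rows(~drop)


def smooth(skel: Skeleton, window: int = 3) -> Skeleton:
    """Centered moving average of node coordinates along each segment;
    segment endpoints (irreducible nodes) are fixed."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    out = skel.copy()
    half = window // 2
    for seg in skel.iter_segments():
        if len(seg) <= 2:
            continue
        xyz = skel.xyz_nm[seg]
        sm = xyz.copy()
        for i in range(1, len(seg) - 1):
            lo, hi = max(0, i - half), min(len(seg), i + half + 1)
            sm[i] = xyz[lo:hi].mean(axis=0)
        out.xyz_nm[seg[1:-1]] = sm[1:-1]
    return out


def postprocess(skel: Skeleton, params: PostprocessParams | None = None) -> Skeleton:
    """The full cleanup pipeline in its canonical order."""
    p = params or PostprocessParams()
    skel = remove_redundant_nodes(skel, p.redundant_eps_nm)
    skel = remove_hair(skel, p.hair_ratio)
    skel = remove_soma_branches(skel)
    skel = resample(skel, p.resample_spacing_nm)
    skel = remove_empty_branches(skel)
    skel = smooth(skel, p.smooth_window)
    return skel
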