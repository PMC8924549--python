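"""Core skeleton container: a rooted forest of nodes with positions and radii.

A :class:`Skeleton` is the SWC-compatible in-memory representation shared by
the tracing, postprocessing, I/O and morphometrics modules.  Nodes carry a
position in nanometres, a radius in nanometres, an SWC structure class and a
parent reference; ``parent_id == -1`` marks a root.  The node table is stored
as parallel numpy arrays for vectorized geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Skeleton"]


@dataclass
class Skeleton:
    """Rooted tree/forest of skeleton nodes.

    Parameters
    ----------
    ids : (n,) int array
        Unique positive node identifiers (SWC column 1).
    structure : (n,) int array
        SWC structure class (0 undefined, 1 soma, 3 dendrite, ...).
    xyz_nm : (n, 3) float array
        Node positions in nanometres.
    radius_nm : (n,) float array
        Node radii in nanometres (non-negative).
    parent_ids : (n,) int array
        Parent node id per node; ``-1`` for roots.
    """

    ids: np.ndarray
    structure: np.ndarray
    xyz_nm: np.ndarray
    radius_nm: np.ndarray
    parent_ids: np.ndarray
    _id_to_row: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.structure = np.asarray(self.structure, dtype=np.int32)
        self.xyz_nm = np.asarray(self.xyz_nm, dtype=np.float64).reshape(-1, 3)
        self.radius_nm = np.asarray(self.radius_nm, dtype=np.float64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.structure) == n and len(self.xyz_nm) == n
                and len(self.radius_nm) == n and len(self.parent_ids) == n):
            raise ValueError("skeleton field lengths disagree")
        if n and len(np.unique(self.ids)) != n:
            raise ValueError("node ids are not unique")
        self._id_to_row = {int(i): r for r, i in enumerate(self.ids)}
        for p in self.parent_ids:
            if p != -1 and int(p) not in self._id_to_row:
                raise ValueError(f"dangling parent id {int(p)}")
        if np.any(self.radius_nm < 0):
            raise ValueError("negative radius")
        self._check_acyclic()

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls) -> "Skeleton":
        z = np.zeros(0)
        return cls(z, z, np.zeros((0, 3)), z, z)

    @classmethod
    def from_arrays(cls, xyz_nm, radius_nm, parent_rows, structure=None) -> "Skeleton":
        """Build from 0-based row-index parents (``-1`` = root); ids become 1..n."""
        n = len(radius_nm)
        parent_rows = np.asarray(parent_rows, dtype=np.int64)
        parent_ids = np.where(parent_rows >= 0, parent_rows + 1, -1)
        if structure is None:
            structure = np.zeros(n, dtype=np.int32)
        return cls(np.arange(1, n + 1), structure, xyz_nm, radius_nm, parent_ids)

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def row_of(self, node_id: int) -> int:
        return self._id_to_row[int(node_id)]

    @property
    def parent_rows(self) -> np.ndarray:
        """Parent as a 0-based row index per node, ``-1`` for roots."""
        out = np.full(self.n_nodes, -1, dtype=np.int64)
        for r, p in enumerate(self.parent_ids):
            if p != -1:
                out[r] = self._id_to_row[int(p)]
        return out

    @property
    def root_rows(self) -> np.ndarray:
        return np.flatnonzero(self.parent_ids == -1)

    @property
    def n_trees(self) -> int:
        return len(self.root_rows)

    def children_map(self) -> list:
        """List of child-row lists, indexed by row, ordered by row."""
        kids = [[] for _ in range(self.n_nodes)]
        for r, p in enumerate(self.parent_rows):
            if p >= 0:
                kids[p].append(r)
        return kids

    def tree_labels(self) -> np.ndarray:
        """0-based tree index per node (roots numbered in row order)."""
        pr = self.parent_rows
        lab = np.full(self.n_nodes, -1, dtype=np.int64)
        for t, root in enumerate(self.root_rows):
            lab[root] = t
        order = self.topological_order()
        for r in order:
            if pr[r] >= 0:
                lab[r] = lab[pr[r]]
        return lab

    def topological_order(self) -> np.ndarray:
        """Rows ordered parents-before-children (iterative DFS from roots)."""
        kids = self.children_map()
        order = []
        for root in self.root_rows:
            stack = [int(root)]
            while stack:
                r = stack.pop()
                order.append(r)
                stack.extend(reversed(kids[r]))
        return np.asarray(order, dtype=np.int64)

    def _check_acyclic(self):
        if len(self.topological_order()) != self.n_nodes:
            raise ValueError("skeleton contains a cycle or unreachable nodes")

    # -- geometry ---------------------------------------------------------

    def edge_rows(self) -> np.ndarray:
        """(m, 2) array of (child_row, parent_row) for every non-root node."""
        pr = self.parent_rows
        child = np.flatnonzero(pr >= 0)
        return np.stack([child, pr[child]], axis=1)

    def edge_lengths_nm(self) -> np.ndarray:
        e = self.edge_rows()
        if len(e) == 0:
            return np.zeros(0)
        return np.linalg.norm(self.xyz_nm[e[:, 0]] - self.xyz_nm[e[:, 1]], axis=1)

    def total_path_length_nm(self) -> float:
        return float(self.edge_lengths_nm().sum())

    # -- structural node classes ------------------------------------------

    def node_degree_classes(self):
        """Return (is_root, n_children) per row."""
        kids = self.children_map()
        n_children = np.array([len(k) for k in kids], dtype=np.int64)
        return self.parent_ids == -1, n_children

    def irreducible_rows(self) -> np.ndarray:
        """Roots, branching nodes (>=2 children) and terminals (0 children)."""
        is_root, n_children = self.node_degree_classes()
        return np.flatnonzero(is_root | (n_children >= 2) | (n_children == 0))

    def branching_rows(self) -> np.ndarray:
        _, n_children = self.node_degree_classes()
        return np.flatnonzero(n_children >= 2)

    def terminal_rows(self) -> np.ndarray:
        _, n_children = self.node_degree_classes()
        return np.flatnonzero(n_children == 0)

    # -- editing helpers ---------------------------------------------------

    def copy(self) -> "Skeleton":
        return Skeleton(self.ids.copy(), self.structure.copy(), self.xyz_nm.copy(),
                        self.radius_nm.copy(), self.parent_ids.copy())

    def keep_rows(self, keep: np.ndarray, reattach: dict | None = None) -> "Skeleton":
        """New skeleton with only ``keep`` rows; removed interior nodes splice
        their children onto the nearest kept ancestor.

        ``reattach`` optionally maps a kept child row to an explicit new
        parent row (used when merging nodes).
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep_mask = keep
        else:
            keep_mask = np.zeros(self.n_nodes, dtype=bool)
            keep_mask[keep] = True
        pr = self.parent_rows
        # climb to nearest kept ancestor
        new_parent = pr.copy()
        for r in self.topological_order():
            p = new_parent[r]
            while p >= 0 and not keep_mask[p]:
                p = new_parent[p]
            new_parent[r] = p
        if reattach:
            for child, parent in reattach.items():
                new_parent[child] = parent
        rows = np.flatnonzero(keep_mask)
        remap = -np.ones(self.n_nodes, dtype=np.int64)
        remap[rows] = np.arange(len(rows))
        parent_rows = np.where(new_parent[rows] >= 0, remap[new_parent[rows]], -1)
        return Skeleton.from_arrays(self.xyz_nm[rows], self.radius_nm[rows],
                                    parent_rows, self.structure[rows])

    def reroot(self, new_root_row: int) -> "Skeleton":
        """Re-root the tree containing ``new_root_row`` by flipping parent
        pointers along the path to the old root.  Other trees are untouched."""
        pr = self.parent_rows
        path = [int(new_root_row)]
        while pr[path[-1]] >= 0:
            path.append(int(pr[path[-1]]))
        new_pr = pr.copy()
        new_pr[path[0]] = -1
        for a, b in zip(path[1:], path[:-1]):
            new_pr[a] = b
        return Skeleton.from_arrays(self.xyz_nm, self.radius_nm, new_pr, self.structure)

    # -- segment iteration -------------------------------------------------

    def iter_segments(self):
        """Yield maximal unbranched paths as row arrays.

        Each path runs from a proximal irreducible node to the next distal
        irreducible node, both included, following parent->child direction.
        A single-node tree yields nothing.
        """
        kids = self.children_map()
        _, n_children = self.node_degree_classes()
        irreducible = np.zeros(self.n_nodes, dtype=bool)
        irreducible[self.irreducible_rows()] = True
        for start in np.flatnonzero(irreducible):
            for child in kids[start]:
                path = [int(start), int(child)]
                while not irreducible[path[-1]]:
                    path.append(kids[path[-1]][0])
                yield np.asarray(path, dtype=np.int64)

    def to_records(self):
        """List of SWC-style tuples (id, structure, x, y, z, radius, parent_id)."""
        return [(int(i), int(s), float(x), float(y), float(z), float(r), int(p))
                for i, s, (x, y, z), r, p in
                zip(self.ids, self.structure, self.xyz_nm, self.radius_nm, self.parent_ids)]
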