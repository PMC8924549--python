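"""NBLAST morphological similarity, implemented from first principles.

Each neuron is reduced to *dotprops*: points resampled at ~1 um spacing,
each with a unit tangent from the dominant principal axis of its k nearest
neighbours.  The raw similarity of a query against a target sums, over query
points, a score function of (distance to the nearest target point, absolute
tangent dot product).  The default score function is the parametric form
``adp * exp(-d / sigma)``; tabulated (distance-bin x |dot|-bin) score
matrices can be loaded from CSV for compatibility with published tables.
Raw scores are normalized by the query's self-score, symmetrized by
averaging the two directions, and ``1 - symmetrized`` (clipped at 0) is the
distance fed to average-linkage hierarchical clustering to call
morphological types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .errors import DegenerateNeuronError, TooSmallError
from .postprocess import resample
from .skeleton import Skeleton

__all__ = [
    "DotProps", "ScoreFunction", "TabulatedScoreFunction",
    "make_dotprops", "nblast_raw", "nblast_matrix", "SimilarityMatrix",
    "cluster", "load_score_table",
]


@dataclass
class DotProps:
    """Point + unit-tangent representation of one neuron, in micrometres."""

    points_um: np.ndarray
    tangents: np.ndarray

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, dtype=np.float64).reshape(-1, 3)
        self.tangents = np.asarray(self.tangents, dtype=np.float64).reshape(-1, 3)
        if len(self.points_um) != len(self.tangents):
            raise ValueError("points/tangents length mismatch")
        norms = np.linalg.norm(self.tangents, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit vectors")

    def __len__(self):
        return len(self.points_um)

    def transformed(self, rotation=None, translation_um=None) -> "DotProps":
        pts, tan = self.points_um, self.tangents
        if rotation is not None:
            R = np.asarray(rotation)
            pts = pts @ R.T
            tan = tan @ R.T
        if translation_um is not None:
            pts = pts + np.asarray(translation_um)
        return DotProps(pts, tan)


@dataclass
class ScoreFunction:
    """Parametric NBLAST score: ``f(d, adp) = adp * exp(-d / sigma_um)``."""

    sigma_um: float = 3.0

    def __call__(self, d_um, adp):
        return np.asarray(adp) * np.exp(-np.asarray(d_um) / self.sigma_um)


@dataclass
class TabulatedScoreFunction:
    """Score looked up in a (distance bin x |dot| bin) matrix.

    ``dist_edges_um`` has len n_d+1 (last edge may be inf); ``adp_edges``
    has len n_a+1 covering [0, 1]; ``table`` is (n_d, n_a).
    """

    dist_edges_um: np.ndarray
    adp_edges: np.ndarray
    table: np.ndarray

    def __call__(self, d_um, adp):
        d_um = np.atleast_1d(np.asarray(d_um, dtype=np.float64))
        adp = np.atleast_1d(np.asarray(adp, dtype=np.float64))
        di = np.clip(np.searchsorted(self.dist_edges_um, d_um, side="right") - 1,
                     0, self.table.shape[0] - 1)
        ai = np.clip(np.searchsorted(self.adp_edges, adp, side="right") - 1,
                     0, self.table.shape[1] - 1)
        return self.table[di, ai]


def load_score_table(path) -> TabulatedScoreFunction:
    """Load a tabulated score matrix from CSV.

    Layout: first column = distance bin lower edges (um), header row =
    |dot| bin lower edges; an implicit upper edge of inf / 1.0 closes the
    last bins.
    """
    df = pd.read_csv(path, index_col=0)
    dist_edges = np.append(df.index.to_numpy(dtype=float), np.inf)
    adp_edges = np.append(df.columns.to_numpy(dtype=float), 1.0)
    return TabulatedScoreFunction(dist_edges, adp_edges, df.to_numpy(dtype=float))


def make_dotprops(skel: Skeleton, spacing_um: float = 1.0, k: int = 5) -> DotProps:
    """Resample a skeleton and attach unit tangents.

    The tangent at each point is the dominant principal axis (sign-free) of
    its ``k`` nearest neighbours (the point included).
    """
    res = resample(skel, spacing_um * 1000.0)
    pts = res.xyz_nm / 1000.0
    return dotprops_from_points(pts, k=k)


def dotprops_from_points(points_um: np.ndarray, k: int = 5) -> DotProps:
    pts = np.asarray(points_um, dtype=np.float64).reshape(-1, 3)
    if len(pts) < k + 1:
        raise TooSmallError(f"need >= {k + 1} points, got {len(pts)}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    tangents = np.empty_like(pts)
    for i in range(len(pts)):
        nb = pts[idx[i]]
        nb = nb - nb.mean(axis=0)
        # dominant principal axis of the local neighborhood
        _, _, vt = np.linalg.svd(nb, full_matrices=False)
        tangents[i] = vt[0]
    return DotProps(pts, tangents)


def nblast_raw(query: DotProps, target: DotProps, fn=None) -> float:
    """Raw one-directional NBLAST score of ``query`` against ``target``."""
    if len(query) == 0 or len(target) == 0:
        raise TooSmallError("empty dotprops")
    fn = fn or ScoreFunction()
    tree = cKDTree(target.points_um)
    d, idx = tree.query(query.points_um)
    adp = np.abs(np.sum(query.tangents * target.tangents[idx], axis=1))
    return float(np.sum(fn(d, adp)))


@dataclass
class SimilarityMatrix:
    """Raw, normalized and symmetrized all-vs-all NBLAST scores."""

    ids: list
    raw: np.ndarray
    normalized: np.ndarray
    symmetrized: np.ndarray

    @property
    def distance(self) -> np.ndarray:
        """``1 - symmetrized`` clipped at 0, zero diagonal — the clustering metric."""
        d = np.clip(1.0 - self.symmetrized, 0.0, None)
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self, which: str = "symmetrized") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.ids, columns=self.ids)


def nblast_matrix(dotprops: list, fn=None, ids=None) -> SimilarityMatrix:
    """All-vs-all scores.  normalized(q, t) = raw(q, t) / raw(q, q);
    symmetrized = mean of the two directions."""
    n = len(dotprops)
    if n < 2:
        raise ValueError("need >= 2 neurons")
    ids = list(ids) if ids is not None else list(range(n))
    fn = fn or ScoreFunction()
    raw = np.empty((n, n))
    for q in range(n):
        for t in range(n):
            raw[q, t] = nblast_raw(dotprops[q], dotprops[t], fn)
    self_scores = np.diag(raw).copy()
    if np.any(self_scores <= 0):
        bad = ids[int(np.argmin(self_scores))]
        raise DegenerateNeuronError(f"neuron {bad} has non-positive self-score")
    normalized = raw / self_scores[:, None]
    symmetrized = 0.5 * (normalized + normalized.T)
    return SimilarityMatrix(ids, raw, normalized, symmetrized)


def cluster(sim: SimilarityMatrix, n_clusters: int):
    """Average-linkage agglomerative clustering of ``1 - symmetrized``.

    Returns (labels, linkage_matrix); labels are 0-based and aligned with
    ``sim.ids``.
    """
    n = len(sim.ids)
    if n_clusters > n:
        raise ValueError("more clusters than neurons")
    condensed = squareform(sim.distance, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return labels, Z
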