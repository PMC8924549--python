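"""Synaptic connectivity: synapse tables, count matrices, community order,
and the morphology-connectivity relationship.

Synapses arrive as a CSV table (one row per synapse with presynaptic and
postsynaptic neuron ids and a position).  The synapse count between two
neurons is the connectedness metric: more synapses means closer.  Counts
map to a distance ``d = 1 / (1 + s)`` (s = symmetrized count), which is fed
to hierarchical clustering; reordering the matrix by the resulting leaf
order exposes the community block structure.  The association between
morphological similarity (NBLAST) and synapse count over neuron pairs is
quantified by a Spearman rank correlation with a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .nblast import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SynapseTable", "ConnectivityMatrix", "read_synapse_csv",
    "build_matrix", "connectivity_distance", "cluster_connectivity",
    "cluster_and_reorder", "morphology_connectivity_association",
]

SYNAPSE_COLUMNS = ["synapse_id", "presyn", "postsyn", "x", "y", "z"]


def read_synapse_csv(path) -> pd.DataFrame:
    """Read a synapse table (header: synapse_id,presyn,postsyn,x,y,z; nm)."""
    df = pd.read_csv(path)
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"synapse CSV missing columns: {missing}")
    return df[SYNAPSE_COLUMNS]


# alias: the canonical in-memory form is just a DataFrame with these columns
SynapseTable = pd.DataFrame


@dataclass
class ConnectivityMatrix:
    """Directed synapse counts between neurons: counts[i, j] = #(i -> j)."""

    ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over ids")
        if np.any(self.counts < 0):
            raise ValueError("negative synapse count")

    def total_synapses(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)

    def permuted(self, perm) -> "ConnectivityMatrix":
        perm = np.asarray(perm)
        return ConnectivityMatrix(self.ids[perm], self.counts[np.ix_(perm, perm)])


def build_matrix(table: pd.DataFrame, ids) -> ConnectivityMatrix:
    """Count synapses per ordered neuron pair.

    Rows referencing ids outside ``ids`` are dropped (with a logged count);
    autapses land on the diagonal.
    """
    ids = np.asarray(list(ids))
    if len(ids) == 0:
        raise ValueError("empty id list")
    if len(np.unique(ids)) != len(ids):
        raise ValueError("ids must be unique")
    index = {v: i for i, v in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    dropped = 0
    for pre, post in zip(table["presyn"], table["postsyn"]):
        try:
            counts[index[pre], index[post]] += 1
        except KeyError:
            dropped += 1
    if dropped:
        logger.warning("dropped %d synapse rows with unknown neuron ids", dropped)
    return ConnectivityMatrix(ids, counts)


def connectivity_distance(m: ConnectivityMatrix) -> np.ndarray:
    """Map symmetrized counts to (0, 1]: d_ij = 1 / (1 + s_ij), d_ii = 0."""
    s = m.counts + m.counts.T
    d = 1.0 / (1.0 + s)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_connectivity(m: ConnectivityMatrix, n_clusters: int):
    """Average-linkage clustering on the connectivity distance.

    Returns (labels, linkage_matrix)."""
    d = connectivity_distance(m)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return labels, Z


def cluster_and_reorder(m: ConnectivityMatrix, order_by):
    """Permute rows and columns identically by a clustering.

    ``order_by`` is either a linkage matrix (leaf order is used) or a label
    vector over ``m.ids`` (stable sort: groups in label order, original
    order within a group).  Returns (reordered matrix, permutation).
    """
    n = len(m.ids)
    order_by = np.asarray(order_by)
    if order_by.ndim == 2:  # linkage matrix
        if order_by.shape[0] != n - 1:
            raise ValueError("linkage does not cover all ids")
        perm = hierarchy.leaves_list(order_by.astype(np.float64))
    else:
        if len(order_by) != n:
            raise ValueError("labels do not cover all ids")
        perm = np.argsort(order_by, kind="stable")
    return m.permuted(perm), np.asarray(perm)


def _spearman(x_rank: np.ndarray, y: np.ndarray) -> float:
    y_rank = rankdata(y)
    xr = x_rank - x_rank.mean()
    yr = y_rank - y_rank.mean()
    denom = np.sqrt((xr ** 2).sum() * (yr ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xr * yr).sum() / denom)


def morphology_connectivity_association(sim: SimilarityMatrix,
                                        m: ConnectivityMatrix,
                                        n_permutations: int = 999,
                                        seed: int = 0):
    """Spearman correlation between NBLAST similarity and synapse count over
    unordered neuron pairs, with a permutation p-value.

    The null permutes neuron identity (rows+columns of the count matrix
    together), preserving both marginal structures.  Returns (rho, p); both
    NaN when either pair vector is constant.
    """
    ids = list(sim.ids)
    if list(m.ids) != ids:
        # align by id
        pos = {v: i for i, v in enumerate(m.ids)}
        try:
            perm = np.asarray([pos[v] for v in ids])
        except KeyError:
            raise ValueError("similarity and connectivity id sets differ")
        m = m.permuted(perm)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    x = sim.symmetrized[iu]
    s = (m.counts + m.counts.T)[iu]
    if np.all(x == x[0]) or np.all(s == s[0]):
        return np.nan, np.nan
    x_rank = rankdata(x)
    rho = _spearman(x_rank, s)
    rng = np.random.default_rng(seed)
    sym = m.counts + m.counts.T
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        s_perm = sym[np.ix_(p, p)][iu]
        r = _spearman(x_rank, s_perm)
        if np.isnan(r) or abs(r) >= abs(rho) - 1e-12:
            hits += 1
    pval = (1 + hits) / (1 + n_permutations)
    return rho, float(pval)
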