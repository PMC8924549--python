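"""Segmentation volumes, bit-packed object masks and the distance field.

A segmentation chunk is a 3D grid of unsigned-integer object ids with an
anisotropic voxel size in nanometres (electron-microscopy voxels are commonly
5 x 5 x 45 nm).  A single object's occupancy is bit-packed to one bit per
voxel — an 8-fold saving over one byte per voxel — before the foreground
voxels are extracted as a point cloud and the distance from boundary field
(DBF) is computed.  The DBF is large at object centres and is what the
tracer's center-hugging penalty and the node radii are built from.

Conventions (stable; they define the packed payload and all geometry):

* arrays are indexed ``labels[i, j, k]`` = (x, y, z); voxel indices 0-based;
* the physical position of global voxel index v is ``(v + 0.5) * spacing_nm``;
* bit packing linearizes x-fastest with little-endian bit significance;
* DBF is the anisotropic Euclidean distance between voxel *centers*, with
  everything outside the mask's bounding box (padded by one voxel) treated
  as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import ndimage

from .errors import EmptyObjectError

__all__ = [
    "SegmentationChunk", "BitPackedMask", "PointCloud",
    "pack_mask", "unpack_mask", "extract_point_cloud", "compute_dbf",
    "read_chunk_h5", "write_chunk_h5",
]


@dataclass
class SegmentationChunk:
    """A labelled subvolume: ``labels[i,j,k]`` is the object id at voxel
    (i, j, k) relative to ``offset_vox`` in the global grid."""

    labels: np.ndarray
    spacing_nm: tuple = (5.0, 5.0, 45.0)
    offset_vox: tuple = (0, 0, 0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a 3D array with all dims >= 1")
        if np.issubdtype(self.labels.dtype, np.signedinteger) and self.labels.min(initial=0) < 0:
            raise ValueError("object ids must be non-negative")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or min(self.spacing_nm) <= 0:
            raise ValueError("spacing_nm must be 3 strictly positive values")
        self.offset_vox = tuple(int(o) for o in self.offset_vox)

    @property
    def dims(self):
        return self.labels.shape

    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]


@dataclass
class BitPackedMask:
    """One object's binary occupancy at 1 bit per voxel.

    ``bits`` holds ceil(nx*ny*nz / 8) bytes; voxel (i, j, k) maps to flat bit
    ``i + nx*j + nx*ny*k`` (x fastest), little-endian within each byte.
    """

    dims: tuple
    spacing_nm: tuple
    offset_vox: tuple
    bits: np.ndarray

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        n = int(np.prod(self.dims))
        if len(self.bits) != (n + 7) // 8:
            raise ValueError("payload size does not match dims")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def n_foreground(self) -> int:
        return int(np.unpackbits(self.bits, count=self.n_voxels, bitorder="little").sum())

    def to_array(self) -> np.ndarray:
        return unpack_mask(self)


@dataclass
class PointCloud:
    """Foreground voxels of one object as global (i, j, k) indices, with the
    per-point distance-from-boundary in nm once :func:`compute_dbf` ran."""

    points_vox: np.ndarray
    spacing_nm: tuple
    dbf_nm: np.ndarray | None = None

    def __post_init__(self):
        self.points_vox = np.asarray(self.points_vox, dtype=np.int64).reshape(-1, 3)
        if self.dbf_nm is not None:
            self.dbf_nm = np.asarray(self.dbf_nm, dtype=np.float64)
            if len(self.dbf_nm) != len(self.points_vox):
                raise ValueError("dbf length mismatch")

    def __len__(self):
        return len(self.points_vox)

    @property
    def positions_nm(self) -> np.ndarray:
        """Physical voxel-center positions, (n, 3) nm."""
        return (self.points_vox + 0.5) * np.asarray(self.spacing_nm)


def pack_mask(chunk: SegmentationChunk, object_id: int) -> BitPackedMask:
    """Bit-pack the occupancy of one object: bit set iff ``labels == object_id``."""
    if object_id == 0:
        raise ValueError("object_id 0 is background, not an object")
    mask = (chunk.labels == object_id)
    flat = mask.flatten(order="F")  # x-fastest linearization
    bits = np.packbits(flat, bitorder="little")
    return BitPackedMask(chunk.dims, chunk.spacing_nm, chunk.offset_vox, bits)


def unpack_mask(mask: BitPackedMask) -> np.ndarray:
    """Inverse of :func:`pack_mask`: boolean array of shape ``mask.dims``."""
    flat = np.unpackbits(mask.bits, count=mask.n_voxels, bitorder="little")
    return flat.reshape(mask.dims, order="F").astype(bool)


def extract_point_cloud(mask: BitPackedMask) -> PointCloud:
    """Foreground voxels as a point cloud in global voxel coordinates,
    lexicographically ordered by (i, j, k).  DBF is left unset."""
    arr = unpack_mask(mask)
    pts = np.argwhere(arr) + np.asarray(mask.offset_vox, dtype=np.int64)
    return PointCloud(pts, mask.spacing_nm)


def compute_dbf(mask: BitPackedMask) -> PointCloud:
    """Point cloud with the distance from boundary field filled in.

    Distance is the anisotropic Euclidean distance from each foreground voxel
    center to the nearest background voxel center; the bounding box is padded
    by one background voxel so border voxels get finite distances.
    """
    arr = unpack_mask(mask)
    if not arr.any():
        raise EmptyObjectError("mask has no foreground voxels")
    padded = np.pad(arr, 1)
    edt = ndimage.distance_transform_edt(padded, sampling=mask.spacing_nm)
    dbf = edt[1:-1, 1:-1, 1:-1][arr]
    pts = np.argwhere(arr) + np.asarray(mask.offset_vox, dtype=np.int64)
    return PointCloud(pts, mask.spacing_nm, dbf)


# -- HDF5 layout ----------------------------------------------------------

def write_chunk_h5(path, chunk: SegmentationChunk, dataset: str = "labels"):
    """Write a chunk as an HDF5 dataset with spacing/offset attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=chunk.labels, compression="gzip")
        d.attrs["spacing_nm"] = chunk.spacing_nm
        d.attrs["offset_vox"] = chunk.offset_vox


def read_chunk_h5(path, dataset: str = "labels") -> SegmentationChunk:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        spacing = tuple(d.attrs.get("spacing_nm", (1.0, 1.0, 1.0)))
        offset = tuple(int(v) for v in d.attrs.get("offset_vox", (0, 0, 0)))
        return SegmentationChunk(d[...], spacing, offset)
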