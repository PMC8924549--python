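"""Synthetic voxel phantoms and circuits with exact ground truth.

The phantom generators rasterize tubes and spheres onto a voxel grid so
that the true centerline polyline, branch topology and (for circuits) the
planted classes and synapse rates are known exactly.  They exist so that
skeletonization, morphometrics, NBLAST clustering and connectivity analysis
can be validated end to end without any imaging data: each generator
records the ground truth it embedded alongside the voxels it emitted, and
the same seed always reproduces the same phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import Skeleton
from .volume import SegmentationChunk

__all__ = [
    "Phantom", "SyntheticCircuit",
    "make_cylinder", "make_y", "make_broken_tube", "make_star",
    "make_soma_with_neurites", "make_circuit",
]


@dataclass
class Phantom:
    """A labelled voxel volume plus the ground truth baked into it."""

    chunk: SegmentationChunk
    truth_centerlines: list          # list of (m, 3) polylines, nm
    truth_topology: dict             # e.g. {"n_branching": 1, "n_terminals": 3}
    params: dict
    rng_seed: int = 0

    @property
    def truth_length_nm(self) -> float:
        total = 0.0
        for line in self.truth_centerlines:
            total += float(np.linalg.norm(np.diff(np.asarray(line), axis=0), axis=1).sum())
        return total


def _rasterize(segments_nm, radii_nm, spheres_nm=(), spacing_nm=(1.0, 1.0, 1.0),
               margin_vox=2):
    """Voxelize a union of capsules (tube segments) and spheres.

    A voxel is foreground when its center lies within radius of any segment
    or inside any sphere.  Returns (labels uint32 with object id 1, lo_vox).
    """
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    pts = [np.asarray(p, dtype=np.float64) for seg in segments_nm for p in seg]
    pts += [np.asarray(c, dtype=np.float64) for c, _ in spheres_nm]
    pts = np.asarray(pts)
    rmax = max(list(radii_nm) + [r for _, r in spheres_nm])
    lo_nm = pts.min(axis=0) - rmax - margin_vox * spacing
    hi_nm = pts.max(axis=0) + rmax + margin_vox * spacing
    lo_vox = np.floor(lo_nm / spacing).astype(np.int64)
    hi_vox = np.ceil(hi_nm / spacing).astype(np.int64)
    dims = hi_vox - lo_vox + 1
    axes = [(np.arange(lo_vox[d], hi_vox[d] + 1) + 0.5) * spacing[d] for d in range(3)]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([cx, cy, cz], axis=-1).reshape(-1, 3)
    mask = np.zeros(len(centers), dtype=bool)
    for (a, b), r in zip(segments_nm, radii_nm):
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(centers - a, axis=1)
        else:
            t = np.clip((centers - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(centers - (a + t[:, None] * ab), axis=1)
        mask |= d <= r
    for c, r in spheres_nm:
        mask |= np.linalg.norm(centers - np.asarray(c, dtype=np.float64), axis=1) <= r
    labels = np.zeros(tuple(dims), dtype=np.uint32)
    labels.reshape(-1)[mask] = 1
    return labels, lo_vox


def _tube_radius_nm(radius_vox, spacing_nm, axis):
    perp = [spacing_nm[d] for d in range(3) if d != axis]
    return radius_vox * min(perp)


_AXIS = {"x": 0, "y": 1, "z": 2}


def make_cylinder(length_vox: int = 100, radius_vox: int = 4,
                  spacing_nm=(1.0, 1.0, 1.0), axis: str = "x",
                  seed: int = 0) -> Phantom:
    """Solid straight tube along a grid axis; truth = the axis polyline."""
    if radius_vox < 2:
        raise ValueError("radius_vox must be >= 2")
    if length_vox < 10 * radius_vox:
        raise ValueError("length_vox must be >= 10 * radius_vox")
    ax = _AXIS[axis]
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    r_nm = _tube_radius_nm(radius_vox, spacing, ax)
    # axis passes through voxel centers, perpendicular center at a voxel center
    center_perp = (radius_vox + 2 + 0.5) * spacing
    p0 = center_perp.copy()
    p0[ax] = 2.5 * spacing[ax]
    p1 = p0.copy()
    p1[ax] += length_vox * spacing[ax]
    labels, lo = _rasterize([(p0, p1)], [r_nm], spacing_nm=spacing)
    chunk = SegmentationChunk(labels, tuple(spacing), tuple(lo))
    return Phantom(chunk, [np.asarray([p0, p1])],
                   {"n_branching": 0, "n_terminals": 2},
                   {"length_vox": length_vox, "radius_vox": radius_vox, "axis": axis},
                   seed)


def make_y(limb_angle_deg: float = 90.0, trunk_len_vox: int = 40,
           limb_len_vox: int = 40, radius_vox: int = 4,
           spacing_nm=(1.0, 1.0, 1.0), seed: int = 0) -> Phantom:
    """Y-shaped phantom: a trunk splitting into two limbs at the given
    mutual angle (in the xy-plane); truth has exactly one branching node."""
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    r_nm = radius_vox * min(spacing[1], spacing[2])
    j = np.array([(trunk_len_vox + radius_vox + 2.5) * spacing[0],
                  (limb_len_vox + radius_vox + 2.5) * spacing[1],
                  (radius_vox + 2.5) * spacing[2]])
    a = j - np.array([trunk_len_vox * spacing[0], 0, 0])
    half = np.deg2rad(limb_angle_deg) / 2.0
    L = limb_len_vox * float(min(spacing[:2]))
    b1 = j + L * np.array([np.cos(half), np.sin(half), 0.0])
    b2 = j + L * np.array([np.cos(half), -np.sin(half), 0.0])
    labels, lo = _rasterize([(a, j), (j, b1), (j, b2)], [r_nm] * 3, spacing_nm=spacing)
    chunk = SegmentationChunk(labels, tuple(spacing), tuple(lo))
    return Phantom(chunk, [np.asarray([a, j]), np.asarray([j, b1]), np.asarray([j, b2])],
                   {"n_branching": 1, "n_terminals": 3,
                    "angle_rad": float(np.deg2rad(limb_angle_deg))},
                   {"limb_angle_deg": limb_angle_deg, "trunk_len_vox": trunk_len_vox,
                    "limb_len_vox": limb_len_vox, "radius_vox": radius_vox},
                   seed)


def make_broken_tube(gap_nm: float = 10.0, length_vox: int = 100,
                     radius_vox: int = 4, spacing_nm=(1.0, 1.0, 1.0),
                     seed: int = 0) -> Phantom:
    """A cylinder with a slab of width ``gap_nm`` removed from its middle:
    two fragments whose reconnection behaviour can be tested against the
    known gap."""
    ph = make_cylinder(length_vox, radius_vox, spacing_nm, "x", seed)
    labels = ph.chunk.labels.copy()
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    lo = np.asarray(ph.chunk.offset_vox)
    p0, p1 = ph.truth_centerlines[0]
    mid = 0.5 * (p0[0] + p1[0])
    xs = (np.arange(labels.shape[0]) + lo[0] + 0.5) * spacing[0]
    cut = np.abs(xs - mid) < gap_nm / 2.0
    labels[cut] = 0
    chunk = SegmentationChunk(labels, ph.chunk.spacing_nm, ph.chunk.offset_vox)
    left = np.asarray([p0, [mid - gap_nm / 2.0, p0[1], p0[2]]])
    right = np.asarray([[mid + gap_nm / 2.0, p0[1], p0[2]], p1])
    return Phantom(chunk, [left, right],
                   {"n_components": 2, "gap_nm": float(gap_nm)},
                   {"gap_nm": gap_nm, "length_vox": length_vox, "radius_vox": radius_vox},
                   seed)


def make_star(n_rays: int = 5, ray_len_vox: int = 40, radius_vox: int = 3,
              spacing_nm=(1.0, 1.0, 1.0), seed: int = 0) -> Phantom:
    """``n_rays`` straight rays radiating from a common center in the
    xy-plane; truth has ``n_rays`` terminals."""
    if n_rays < 2:
        raise ValueError("need >= 2 rays")
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    r_nm = radius_vox * float(min(spacing[:2]))
    L = ray_len_vox * float(min(spacing[:2]))
    c = np.array([(ray_len_vox + radius_vox + 2.5) * spacing[0],
                  (ray_len_vox + radius_vox + 2.5) * spacing[1],
                  (radius_vox + 2.5) * spacing[2]])
    segs, lines = [], []
    for k in range(n_rays):
        th = 2 * np.pi * k / n_rays
        tip = c + L * np.array([np.cos(th), np.sin(th), 0.0])
        segs.append((c, tip))
        lines.append(np.asarray([c, tip]))
    labels, lo = _rasterize(segs, [r_nm] * n_rays, spacing_nm=spacing)
    chunk = SegmentationChunk(labels, tuple(spacing), tuple(lo))
    return Phantom(chunk, lines,
                   {"n_terminals": n_rays},
                   {"n_rays": n_rays, "ray_len_vox": ray_len_vox, "radius_vox": radius_vox},
                   seed)


def make_soma_with_neurites(soma_radius_vox: int = 8, n_neurites: int = 3,
                            neurite_len_vox: int = 40, neurite_radius_vox: int = 2,
                            spacing_nm=(1.0, 1.0, 1.0), seed: int = 0) -> Phantom:
    """A spherical soma with thin neurites radiating from it; the soma
    center and radius are recorded so soma-branch cleanup can be checked."""
    spacing = np.asarray(spacing_nm, dtype=np.float64)
    r_soma = soma_radius_vox * float(min(spacing))
    r_tube = neurite_radius_vox * float(min(spacing))
    L = (soma_radius_vox + neurite_len_vox) * float(min(spacing[:2]))
    side = soma_radius_vox + neurite_len_vox + neurite_radius_vox + 2
    c = np.array([(side + 0.5) * spacing[0], (side + 0.5) * spacing[1],
                  (soma_radius_vox + 2.5) * spacing[2]])
    segs, lines = [], []
    for k in range(n_neurites):
        th = 2 * np.pi * k / n_neurites
        tip = c + L * np.array([np.cos(th), np.sin(th), 0.0])
        segs.append((c, tip))
        lines.append(np.asarray([c, tip]))
    labels, lo = _rasterize(segs, [r_tube] * n_neurites,
                            spheres_nm=[(c, r_soma)], spacing_nm=spacing)
    chunk = SegmentationChunk(labels, tuple(spacing), tuple(lo))
    return Phantom(chunk, lines,
                   {"n_terminals": n_neurites, "soma_center_nm": c.tolist(),
                    "soma_radius_nm": float(r_soma)},
                   {"soma_radius_vox": soma_radius_vox, "n_neurites": n_neurites},
                   seed)


# -- circuits -------------------------------------------------------------


@dataclass
class SyntheticCircuit:
    """Planted-structure circuit: per-class archetype skeletons with
    per-neuron jitter, and Poisson synapse counts per ordered pair with a
    higher rate within classes than between them."""

    skeletons: list
    labels: np.ndarray
    synapse_table: pd.DataFrame
    lam_within: float
    lam_between: float
    rng_seed: int = 0

    @property
    def n_neurons(self) -> int:
        return len(self.skeletons)


def _archetype_polyline(rng, center_um, n_nodes=60, step_um=3.0, drift=0.25):
    """Smooth random-walk polyline in um: a persistent direction perturbed
    each step, anchored at ``center_um``."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    pts = [np.zeros(3)]
    for _ in range(n_nodes - 1):
        v = v + drift * rng.normal(size=3)
        v /= np.linalg.norm(v)
        pts.append(pts[-1] + step_um * v)
    pts = np.asarray(pts)
    return pts - pts.mean(axis=0) + np.asarray(center_um)


def make_circuit(n_neurons: int = 40, n_classes: int = 4,
                 lam_within: float = 8.0, lam_between: float = 0.5,
                 seed: int = 0, jitter_um: float = 1.0,
                 class_separation_um: float = 300.0,
                 n_nodes: int = 60, step_um: float = 3.0) -> SyntheticCircuit:
    """Generate a circuit with planted morphological classes and planted
    community structure in its synaptic connectivity.

    Each class has one archetype skeleton (a smooth random walk placed on a
    ring of radius ``class_separation_um``); each neuron is its class
    archetype with isotropic Gaussian node jitter of ``jitter_um``.  The
    synapse count of each ordered pair is Poisson with rate ``lam_within``
    inside a class and ``lam_between`` across classes, so morphologically
    similar neurons are more strongly connected whenever
    ``lam_within > lam_between``.
    """
    if n_classes > n_neurons:
        raise ValueError("more classes than neurons")
    if lam_within <= 0 or lam_between < 0:
        raise ValueError("rates must be lam_within > 0, lam_between >= 0")
    rng = np.random.default_rng(seed)
    archetypes = []
    for c in range(n_classes):
        th = 2 * np.pi * c / n_classes
        center = class_separation_um * np.array([np.cos(th), np.sin(th), 0.0])
        archetypes.append(_archetype_polyline(rng, center, n_nodes, step_um))
    labels = np.array([i % n_classes for i in range(n_neurons)])
    skeletons = []
    for i in range(n_neurons):
        pts_um = archetypes[labels[i]] + rng.normal(scale=jitter_um,
                                                    size=(n_nodes, 3))
        xyz_nm = pts_um * 1000.0
        parent = np.arange(-1, n_nodes - 1)
        skeletons.append(Skeleton.from_arrays(
            xyz_nm, np.full(n_nodes, 500.0), parent))
    rows = []
    sid = 1
    for i in range(n_neurons):
        for j in range(n_neurons):
            if i == j:
                continue
            lam = lam_within if labels[i] == labels[j] else lam_between
            count = rng.poisson(lam) if lam > 0 else 0
            for _ in range(count):
                a = skeletons[i].xyz_nm[rng.integers(n_nodes)]
                b = skeletons[j].xyz_nm[rng.integers(n_nodes)]
                pos = 0.5 * (a + b) + rng.normal(scale=100.0, size=3)
                rows.append((sid, i + 1, j + 1, pos[0], pos[1], pos[2]))
                sid += 1
    table = pd.DataFrame(rows, columns=["synapse_id", "presyn", "postsyn",
                                        "x", "y", "z"])
    return SyntheticCircuit(skeletons, labels, table, lam_within, lam_between, seed)
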