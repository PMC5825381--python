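"""ROI mask utilities: hippocampal long-axis split and ROI-restricted
searchlight sphere enumeration."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def split_long_axis(
    mask: np.ndarray, anterior_fraction: float = 0.35, axis: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into anterior/posterior parts along one axis.

    The slices along ``axis`` that contain at least one mask voxel are
    counted, and the anterior part covers the first
    ``round(anterior_fraction * n_occupied_slices)`` of them (round half
    up); the default 0.35 labels the anterior 35% of the hippocampus.
    The two outputs partition the input exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if not 0.0 < anterior_fraction < 1.0:
        raise ValueError("anterior_fraction must be in (0, 1)")
    other_axes = tuple(a for a in range(mask.ndim) if a != axis)
    occupied = np.flatnonzero(mask.any(axis=other_axes))
    if len(occupied) < 2:
        raise ValueError("mask spans a single slice; cannot split")
    n_anterior = int(math.floor(anterior_fraction * len(occupied) + 0.5))
    n_anterior = min(max(n_anterior, 1), len(occupied) - 1)
    anterior_slices = set(occupied[:n_anterior].tolist())
    slice_index = np.arange(mask.shape[axis])
    in_anterior = np.isin(slice_index, list(anterior_slices))
    shape = [1] * mask.ndim
    shape[axis] = mask.shape[axis]
    in_anterior = in_anterior.reshape(shape)
    anterior = mask & in_anterior
    posterior = mask & ~in_anterior
    return anterior, posterior


@dataclass
class SphereSet:
    """Searchlight spheres restricted to one ROI.

    ``voxel_coords`` lists the ROI voxels in C-scan order (the order of
    ``volume[mask]``); ``members[i]`` holds, for the sphere centred on
    ROI voxel ``i``, the ROI-voxel indices within ``radius`` (Euclidean,
    in voxel units).  Spheres near the ROI border simply contain fewer
    voxels — membership never leaves the ROI.
    """

    voxel_coords: np.ndarray
    members: list[np.ndarray]
    radius: float

    @property
    def n_centers(self) -> int:
        return len(self.members)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets within Euclidean ``radius`` of the origin
    (123 lattice points for radius 3)."""
    r = int(math.floor(radius))
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def enumerate_spheres(mask: np.ndarray, radius_voxels: float = 3.0) -> SphereSet:
    """Build the ROI-restricted searchlight index for one mask.

    Every ROI voxel is a sphere centre exactly once; every member voxel
    lies inside the ROI.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    coords = np.argwhere(mask)
    index_of = -np.ones(mask.shape, dtype=np.int64)
    index_of[tuple(coords.T)] = np.arange(len(coords))
    offsets = sphere_offsets(radius_voxels)
    shape = np.array(mask.shape)
    members: list[np.ndarray] = []
    for center in coords:
        pts = center + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        idx = index_of[tuple(pts.T)]
        members.append(np.sort(idx[idx >= 0]))
    return SphereSet(voxel_coords=coords, members=members, radius=radius_voxels)
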