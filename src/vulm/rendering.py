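"""Super-resolution rendering of tracks onto the λ/20 grid.

Tracks are rasterized as polylines: each segment between consecutive
smoothed points is supersampled at quarter-voxel steps, and the traversed
voxels accumulate a density count (one per track passage) and the segment
speeds (averaged per voxel into the velocity map).  The density image is
Gaussian-filtered with σ = 0.8 render-voxels; the velocity map is median-
filtered over supported voxels for hemodynamic analysis (Gaussian smoothing
of the velocity map is for display only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import RENDER_VOXEL_MM, GridSpec, logger
from .tracking import Track

DENSITY_GAUSSIAN_SIGMA = 0.8  # render-voxels


@dataclass
class ULMImage:
    """Super-resolution vessel-density image on an isotropic render grid."""

    density: np.ndarray       # 3-D nonnegative
    render_voxel: float = RENDER_VOXEL_MM  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.density.shape, self.render_voxel)


@dataclass
class VelocityMap:
    """Voxelwise mean microbubble speed and its per-voxel support count."""

    speed: np.ndarray          # mm/s; 0 where no track passed
    support_count: np.ndarray  # contributing segments per voxel
    render_voxel: float = RENDER_VOXEL_MM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.speed.shape, self.render_voxel)


def render_grid(beamform_grid: GridSpec, factor: int = 10) -> GridSpec:
    """Render grid covering the beamformed domain at ``voxel/factor``."""
    return GridSpec(tuple(int(n * factor) for n in beamform_grid.shape),
                    beamform_grid.voxel_size / factor)


def _segment_voxels(p0: np.ndarray, p1: np.ndarray, grid: GridSpec
                    ) -> np.ndarray:
    """Voxel indices traversed by one segment (¼-voxel supersampling)."""
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(np.ceil(length / (0.25 * grid.voxel_size))) + 1)
    pts = np.linspace(p0, p1, n)
    idx = np.round(grid.position_to_index(pts)).astype(np.int64)
    shape = np.asarray(grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx[ok]


def _track_voxel_sets(track: Track, grid: GridSpec):
    """Per-segment traversed voxels (raveled) and the track's unique set."""
    pts = track.smoothed_points
    if pts is None:
        raise ValueError("tracks must be smoothed before rendering")
    shape = grid.shape
    seg_ravel = []
    for i in range(len(pts) - 1):
        vox = _segment_voxels(pts[i], pts[i + 1], grid)
        seg_ravel.append(
            np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
            if len(vox) else np.empty(0, dtype=np.int64))
    all_vox = np.unique(np.concatenate(seg_ravel)) if seg_ravel \
        else np.empty(0, dtype=np.int64)
    return seg_ravel, all_vox


def render_density(tracks: list[Track], grid: GridSpec,
                   gaussian_sigma: float = DENSITY_GAUSSIAN_SIGMA
                   ) -> ULMImage:
    """Rasterize track polylines into a density image.

    Every voxel traversed by a track's polyline is incremented once per
    track passage; the image is then Gaussian-filtered (σ in render-voxel
    units; pass 0 to skip filtering).  Track points outside the grid are
    clipped and logged.
    """
    density = np.zeros(grid.shape, dtype=np.float32).ravel()
    clipped = 0
    for tr in tracks:
        seg_ravel, all_vox = _track_voxel_sets(tr, grid)
        if not grid.contains(tr.smoothed_points).all():
            clipped += 1
        np.add.at(density, all_vox, 1.0)
    if clipped:
        logger.info("render_density: %d tracks partially outside grid "
                    "(clipped)", clipped)
    density = density.reshape(grid.shape)
    if gaussian_sigma > 0:
        density = ndimage.gaussian_filter(density, sigma=gaussian_sigma)
    return ULMImage(density, grid.voxel_size)


def _masked_median3(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """3³ median over supported voxels only; unsupported voxels stay 0.

    Works slab-by-slab along the depth axis to bound memory.
    """
    nz, nx, ny = values.shape
    pad_v = np.pad(values, 1, mode="constant")
    pad_m = np.pad(support, 1, mode="constant")
    out = np.zeros_like(values)
    slab = max(1, int(4e6 // (nx * ny)))  # voxels per slab chunk
    offs = [(dz, dx, dy) for dz in range(3) for dx in range(3)
            for dy in range(3)]
    for z0 in range(0, nz, slab):
        z1 = min(nz, z0 + slab)
        stack_v = np.empty((27, z1 - z0, nx, ny), dtype=np.float32)
        stack_m = np.empty((27, z1 - z0, nx, ny), dtype=bool)
        for i, (dz, dx, dy) in enumerate(offs):
            stack_v[i] = pad_v[z0 + dz:z1 + dz, dx:nx + dx, dy:ny + dy]
            stack_m[i] = pad_m[z0 + dz:z1 + dz, dx:nx + dx, dy:ny + dy]
        stack_v[~stack_m] = np.inf
        stack_v.sort(axis=0)
        k = stack_m.sum(axis=0)
        ksafe = np.maximum(k, 1)
        lo = np.take_along_axis(stack_v, ((ksafe - 1) // 2)[None], axis=0)[0]
        hi = np.take_along_axis(stack_v, (ksafe // 2)[None], axis=0)[0]
        med = 0.5 * (lo + hi)
        out[z0:z1] = np.where(k > 0, med, 0.0)
    return np.where(support, out, 0.0)


def render_velocity(tracks: list[Track], grid: GridSpec,
                    smoothing: str = "median",
                    gaussian_sigma: float = DENSITY_GAUSSIAN_SIGMA
                    ) -> VelocityMap:
    """Rasterize per-segment speeds into a voxelwise mean-speed map.

    Each voxel traversed by a track segment accumulates that segment's
    speed; the voxel value is the mean of its contributions.  With
    ``smoothing='median'`` (the hemodynamic-analysis default) a 3³ median
    over supported voxels removes speeds from erroneous tracks;
    ``'gaussian'`` smooths for display; ``'none'`` returns the raw means.
    """
    if smoothing not in ("median", "gaussian", "none"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    speed_sum = np.zeros(grid.shape, dtype=np.float64).ravel()
    count = np.zeros(grid.shape, dtype=np.int32).ravel()
    for tr in tracks:
        if tr.segment_speeds is None:
            raise ValueError("tracks must carry segment_speeds")
        seg_ravel, _ = _track_voxel_sets(tr, grid)
        for i, rav in enumerate(seg_ravel):
            np.add.at(speed_sum, rav, float(tr.segment_speeds[i]))
            np.add.at(count, rav, 1)
    count = count.reshape(grid.shape)
    speed = np.zeros(grid.shape, dtype=np.float32)
    np.divide(speed_sum.reshape(grid.shape), count, out=speed,
              where=count > 0, casting="unsafe")
    support = count > 0
    if smoothing == "median":
        speed = _masked_median3(speed, support)
    elif smoothing == "gaussian":
        speed = ndimage.gaussian_filter(speed, sigma=gaussian_sigma)
    return VelocityMap(speed, count, grid.voxel_size)


def maximum_intensity_projection(image: np.ndarray, axis: int = 2
                                 ) -> np.ndarray:
    """MIP along one axis, for visual checks of rendered volumes."""
    return np.max(image, axis=axis)
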