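"""Synthetic 3-D vasculature, microbubble transits, and volume stacks.

The generator provides the ground truth the rest of the pipeline is tested
against: a bilaterally (optionally exactly) symmetric network of straight
vessel segments with per-segment flow speeds, a tumor model that removes
vessels from a core and slows peripheral flow, Poisson microbubble transits
advected along centerlines, and beamformed-like intensity stacks consisting
of Gaussian bubble blobs over static tissue clutter plus sensor noise.

Healthy cerebral flow is drawn from the 1–30 mm/s range; tumor-peripheral
flow from 0.1–0.8 mm/s; bubble density defaults to the 60–100 per-volume
regime at full field-of-view scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (BEAMFORM_VOXEL_MM, DEFAULT_VOLUME_RATE_HZ, LAMBDA_MM,
                   GridSpec, VolumeStack, logger)

HEALTHY_SPEED_RANGE_MM_S: tuple[float, float] = (1.0, 30.0)
TUMOR_SPEED_RANGE_MM_S: tuple[float, float] = (0.1, 0.8)
MEAN_MB_PER_VOLUME_FULL_FOV: float = 80.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSegment:
    """Straight vessel segment with constant radius and centerline speed."""

    start_point: tuple[float, float, float]  # mm (z, x, y)
    end_point: tuple[float, float, float]    # mm
    radius: float                            # mm
    centerline_speed: float                  # mm/s
    hemisphere_tag: str                      # left | right | midline

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.centerline_speed < 0:
            raise ValueError("centerline_speed must be nonnegative")
        if np.allclose(self.start_point, self.end_point):
            raise ValueError("degenerate segment: start == end")
        if self.hemisphere_tag not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere_tag {self.hemisphere_tag!r}")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_point,
                                                self.start_point)))

    @property
    def direction(self) -> np.ndarray:
        d = np.subtract(self.end_point, self.start_point)
        return d / np.linalg.norm(d)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.start_point) +
                      np.asarray(self.end_point))


@dataclass
class VesselNetwork:
    """Collection of segments inside a rectangular domain.

    The symmetry plane is the lateral mid-plane ``x = extent_x / 2`` unless
    stated otherwise; bilateral mirroring maps ``x → extent_x − x``.
    """

    segments: list[VesselSegment]
    domain_extent: tuple[float, float, float]  # mm (z, x, y)
    symmetry_plane_lateral_mm: float | None = None

    def __post_init__(self) -> None:
        if self.symmetry_plane_lateral_mm is None:
            self.symmetry_plane_lateral_mm = self.domain_extent[1] / 2.0
        ext = np.asarray(self.domain_extent)
        for seg in self.segments:
            for p in (seg.start_point, seg.end_point):
                if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > ext):
                    raise ValueError(f"segment endpoint {p} outside domain")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.segments):
            rows.append({
                "segment_id": i,
                "z0_mm": s.start_point[0], "x0_mm": s.start_point[1],
                "y0_mm": s.start_point[2],
                "z1_mm": s.end_point[0], "x1_mm": s.end_point[1],
                "y1_mm": s.end_point[2],
                "radius_mm": s.radius,
                "speed_mm_s": s.centerline_speed,
                "hemisphere": s.hemisphere_tag,
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   domain_extent: tuple[float, float, float]) -> "VesselNetwork":
        segs = [VesselSegment(
            (r.z0_mm, r.x0_mm, r.y0_mm), (r.z1_mm, r.x1_mm, r.y1_mm),
            r.radius_mm, r.speed_mm_s, r.hemisphere)
            for r in df.itertuples()]
        return cls(segs, domain_extent)


@dataclass(frozen=True)
class TumorSpec:
    """Spherical lesion: vessel dropout in the core, slowed flow at the rim."""

    center: tuple[float, float, float]          # mm
    core_radius: float                          # mm
    periphery_radius: float                     # mm
    periphery_speed_range: tuple[float, float] = TUMOR_SPEED_RANGE_MM_S
    dropout_fraction_in_core: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.core_radius <= self.periphery_radius):
            raise ValueError("need 0 <= core_radius <= periphery_radius")
        lo, hi = self.periphery_speed_range
        if lo < 0 or hi < lo:
            raise ValueError("bad periphery_speed_range")
        if not (0 <= self.dropout_fraction_in_core <= 1):
            raise ValueError("dropout fraction must be in [0, 1]")


@dataclass
class MBGroundTruth:
    """Per-volume microbubble records: position, true speed, parent segment."""

    records: pd.DataFrame  # volume_index, bubble_id, z_mm, x_mm, y_mm,
    #                        speed_mm_s, segment_id
    volume_rate: float = DEFAULT_VOLUME_RATE_HZ
    n_volumes: int = 0

    def mean_count_per_volume(self) -> float:
        if self.n_volumes == 0:
            return 0.0
        return len(self.records) / self.n_volumes

    def positions(self, volume_index: int) -> np.ndarray:
        sub = self.records[self.records.volume_index == volume_index]
        return sub[["z_mm", "x_mm", "y_mm"]].to_numpy()


@dataclass(frozen=True)
class BranchingParams:
    """Shape parameters of the random binary vessel trees."""

    n_levels: int = 4
    root_length_fraction: float = 0.45   # of the shortest domain side
    length_decay: float = 0.72
    root_radius_mm: float = 0.08
    radius_decay: float = 0.78
    branch_angle_deg: float = 35.0
    angle_jitter_deg: float = 15.0
    sinus: bool = True                   # dominant midline vessel
    sinus_radius_mm: float = 0.15


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def _rotate_away(direction: np.ndarray, angle_rad: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by ``angle_rad`` about a random orthogonal axis."""
    d = direction / np.linalg.norm(direction)
    # random unit vector orthogonal to d
    v = rng.standard_normal(3)
    v -= v @ d * d
    n = np.linalg.norm(v)
    if n < 1e-12:  # pathological draw; retry deterministically
        v = np.array([d[1], -d[0], 0.0])
        n = np.linalg.norm(v) or 1.0
    v /= n
    return np.cos(angle_rad) * d + np.sin(angle_rad) * v


def _clip_endpoint(start: np.ndarray, end: np.ndarray,
                   extent: np.ndarray, margin: float) -> np.ndarray:
    """Pull an endpoint back inside the domain, keeping start fixed."""
    lo = np.full(3, margin)
    hi = extent - margin
    return np.clip(end, lo, hi)


def _grow_tree(root: np.ndarray, direction: np.ndarray, params: BranchingParams,
               extent: np.ndarray, rng: np.random.Generator,
               root_length: float) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Recursive binary branching; returns (start, end, radius) triples."""
    out: list[tuple[np.ndarray, np.ndarray, float]] = []
    margin = 0.02 * float(extent.min())
    stack = [(root, direction, root_length, params.root_radius_mm, 0)]
    while stack:
        start, d, length, radius, level = stack.pop()
        end = _clip_endpoint(start, start + d * length, extent, margin)
        if np.linalg.norm(end - start) < 0.25 * length:
            continue  # ran into a wall; prune this branch
        out.append((start, end, radius))
        if level + 1 >= params.n_levels:
            continue
        base = np.deg2rad(params.branch_angle_deg)
        jit = np.deg2rad(params.angle_jitter_deg)
        d_new = (end - start) / np.linalg.norm(end - start)
        for _ in range(2):
            ang = base + rng.uniform(-jit, jit)
            child_dir = _rotate_away(d_new, ang, rng)
            stack.append((end, child_dir, length * params.length_decay,
                          radius * params.radius_decay, level + 1))
    return out


def _mirror_point(p: np.ndarray, plane_x: float) -> np.ndarray:
    q = p.copy()
    q[1] = 2.0 * plane_x - q[1]
    return q


def generate_vessel_network(
        domain_extent: tuple[float, float, float],
        n_trees: int = 3,
        branching_params: BranchingParams | None = None,
        speed_range: tuple[float, float] = HEALTHY_SPEED_RANGE_MM_S,
        mirror: bool = True,
        seed: int = 0) -> VesselNetwork:
    """Generate a random branching vessel network.

    With ``mirror=True`` the trees are grown in the left half of the domain
    and every segment is duplicated by exact reflection about the lateral
    mid-plane, so the centerline raster of the lesion-free network is
    bilaterally symmetric by construction.  An optional dominant midline
    vessel runs along the symmetry plane.

    Parameters
    ----------
    speed_range : (min, max) mm/s
        Per-segment centerline speeds are drawn uniformly from this range;
        the default covers healthy cerebral flow, 1–30 mm/s.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    lo, hi = speed_range
    if not (0 <= lo <= hi <= 100):
        raise ValueError("speed_range must lie within [0, 100] mm/s")
    params = branching_params or BranchingParams()
    extent = np.asarray(domain_extent, dtype=float)
    root_length = params.root_length_fraction * float(extent.min())
    if root_length <= 4 * BEAMFORM_VOXEL_MM or np.any(extent <= 0):
        raise ValueError(
            f"domain {tuple(extent)} mm too small to contain one vessel "
            f"segment of length {root_length:.3f} mm")
    rng = np.random.default_rng(seed)
    plane_x = extent[1] / 2.0

    geoms: list[tuple[np.ndarray, np.ndarray, float]] = []
    # grow trees in the left half (x < plane) only; mirror afterwards
    half_hi = plane_x if mirror else extent[1]
    half_extent = extent.copy()
    half_extent[1] = half_hi
    for _ in range(n_trees):
        root = np.array([
            rng.uniform(0.08, 0.25) * extent[0],
            rng.uniform(0.15, 0.80) * half_hi,
            rng.uniform(0.15, 0.85) * extent[2],
        ])
        direction = np.array([1.0, rng.uniform(-0.4, 0.4),
                              rng.uniform(-0.4, 0.4)])
        direction /= np.linalg.norm(direction)
        geoms.extend(_grow_tree(root, direction, params, half_extent, rng,
                                root_length))
    if not geoms:
        raise ValueError("domain too small: no vessel segment could be placed")

    segments: list[VesselSegment] = []
    for start, end, radius in geoms:
        speed = float(rng.uniform(lo, hi))
        tag = "left" if 0.5 * (start[1] + end[1]) < plane_x else "right"
        segments.append(VesselSegment(tuple(start), tuple(end), radius,
                                      speed, tag))
        if mirror:
            segments.append(VesselSegment(
                tuple(_mirror_point(start, plane_x)),
                tuple(_mirror_point(end, plane_x)),
                radius, speed, "right"))
    if params.sinus:
        z = 0.12 * extent[0]
        speed = float(rng.uniform(lo, hi))
        segments.append(VesselSegment(
            (z, plane_x, 0.05 * extent[2]), (z, plane_x, 0.95 * extent[2]),
            params.sinus_radius_mm, speed, "midline"))
    return VesselNetwork(segments, tuple(extent), plane_x)


def apply_tumor_model(network: VesselNetwork, tumor: TumorSpec,
                      seed: int = 0) -> VesselNetwork:
    """Apply a spherical lesion to a vessel network.

    A fraction ``dropout_fraction_in_core`` of the segments whose midpoint
    lies within ``core_radius`` of the tumor center is removed; surviving
    segments with midpoints inside ``periphery_radius`` have their speeds
    resampled into ``periphery_speed_range``.  Segments outside the
    periphery are untouched.
    """
    center = np.asarray(tumor.center, dtype=float)
    if np.any(center < 0) or np.any(center > np.asarray(network.domain_extent)):
        raise ValueError("tumor center outside domain")
    rng = np.random.default_rng(seed)
    dist = np.array([np.linalg.norm(s.midpoint - center)
                     for s in network.segments])
    in_core = np.flatnonzero(dist <= tumor.core_radius)
    n_drop = int(round(tumor.dropout_fraction_in_core * len(in_core)))
    drop = set(rng.choice(in_core, size=n_drop, replace=False).tolist()
               ) if n_drop else set()
    lo, hi = tumor.periphery_speed_range
    new_segments: list[VesselSegment] = []
    for i, seg in enumerate(network.segments):
        if i in drop:
            continue
        if dist[i] <= tumor.periphery_radius:
            seg = replace(seg, centerline_speed=float(rng.uniform(lo, hi)))
        new_segments.append(seg)
    return VesselNetwork(new_segments, network.domain_extent,
                         network.symmetry_plane_lateral_mm)


# ---------------------------------------------------------------------------
# Microbubble transits
# ---------------------------------------------------------------------------

def simulate_mb_transits(network: VesselNetwork, n_volumes: int,
                         volume_rate: float = DEFAULT_VOLUME_RATE_HZ,
                         mean_mb_per_volume: float = MEAN_MB_PER_VOLUME_FULL_FOV,
                         seed: int = 0) -> MBGroundTruth:
    """Simulate bubble transits along segment centerlines.

    Bubbles enter each segment as a seeded Poisson process (entry rates
    weighted by segment length so the expected concurrent count equals
    ``mean_mb_per_volume``), advect along the centerline at the segment
    speed, and vanish at the segment end.  Each bubble carries one fixed
    radial offset drawn uniformly within the vessel radius, perpendicular to
    the centerline, so its per-frame displacement is exactly
    ``speed / volume_rate`` along the centerline direction.
    """
    if network.n_segments == 0:
        raise ValueError("network has zero segments")
    if mean_mb_per_volume <= 0:
        raise ValueError("mean_mb_per_volume must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([s.length for s in network.segments])
    conc = mean_mb_per_volume * lengths / lengths.sum()  # target per segment

    rows: list[tuple] = []
    bubble_id = 0
    for sid, seg in enumerate(network.segments):
        L = seg.length
        v = seg.centerline_speed
        d = seg.direction
        # orthonormal frame perpendicular to the centerline
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 \
            else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, ref); e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        step = v / volume_rate  # mm per frame along the centerline
        if v > 0:
            lifetime = L / step  # frames on the segment
            rate = conc[sid] / lifetime  # entries per frame
            n_entries = rng.poisson(rate * (n_volumes + lifetime))
            entries = rng.uniform(-lifetime, n_volumes, size=n_entries)
            arc0 = np.zeros(n_entries)
        else:
            # stationary bubbles: present for the whole run at fixed arcs
            n_entries = rng.poisson(conc[sid])
            entries = np.full(n_entries, -1e-9)
            arc0 = rng.uniform(0, L, size=n_entries)
            lifetime = float(n_volumes)
        start = np.asarray(seg.start_point)
        for b in range(n_entries):
            r_off = seg.radius * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            offset = r_off * (np.cos(phi) * e1 + np.sin(phi) * e2)
            t0 = entries[b]
            first = max(0, int(np.ceil(t0)))
            last = min(n_volumes - 1, int(np.floor(t0 + lifetime)))
            for t in range(first, last + 1):
                arc = arc0[b] + (t - t0) * step
                if arc < 0 or arc > L:
                    continue
                pos = start + d * arc + offset
                rows.append((t, bubble_id, pos[0], pos[1], pos[2], v, sid))
            bubble_id += 1
    df = pd.DataFrame(rows, columns=["volume_index", "bubble_id", "z_mm",
                                     "x_mm", "y_mm", "speed_mm_s",
                                     "segment_id"])
    df = df.sort_values(["volume_index", "bubble_id"], kind="stable",
                        ignore_index=True)
    return MBGroundTruth(df, volume_rate=volume_rate, n_volumes=n_volumes)


# ---------------------------------------------------------------------------
# Volume-stack synthesis
# ---------------------------------------------------------------------------

def _tissue_field(shape: tuple[int, int, int], amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Static, spatially smooth, strictly positive clutter field."""
    if amplitude == 0:
        return np.zeros(shape)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    f -= f.min()
    peak = f.max()
    if peak > 0:
        f /= peak
    return amplitude * (0.3 + 0.7 * f)


def synthesize_volume_stack(truth: MBGroundTruth, grid: GridSpec,
                            psf_fwhm_mm: float = LAMBDA_MM,
                            tissue_amplitude: float = 0.0,
                            noise_sigma: float = 0.0,
                            seed: int = 0) -> VolumeStack:
    """Rasterize bubble ground truth into a beamformed-like intensity stack.

    Each bubble contributes a unit-peak Gaussian blob with the stated FWHM
    (default one wavelength, i.e. two half-wavelength voxels) centered at
    its sub-voxel position.  A static smooth tissue field (identical in
    every frame, hence rank 1 in time) and i.i.d. Gaussian sensor noise are
    added; the result is clipped at zero so intensities are nonnegative.
    Bubbles outside the grid are clipped silently (counted in the log).
    """
    n_volumes = truth.n_volumes
    shape = tuple(grid.shape)
    sigma_vox = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / grid.voxel_size
    half = int(np.ceil(4.0 * sigma_vox))
    rng = np.random.default_rng(seed)
    tissue = _tissue_field(shape, tissue_amplitude, rng)

    data = np.empty(shape + (n_volumes,), dtype=np.float32)
    rec = truth.records
    clipped = 0
    by_vol = rec.groupby("volume_index") if len(rec) else None
    ax = [np.arange(n) for n in shape]
    for t in range(n_volumes):
        frame = tissue.copy()
        if by_vol is not None and t in by_vol.groups:
            sub = by_vol.get_group(t)
            pos = sub[["z_mm", "x_mm", "y_mm"]].to_numpy()
            idx = grid.position_to_index(pos)
            for c in idx:
                if np.any(c < -half) or np.any(c > np.array(shape) - 1 + half):
                    clipped += 1
                    continue
                lo = np.maximum(np.ceil(c - half).astype(int), 0)
                hi = np.minimum(np.floor(c + half).astype(int),
                                np.array(shape) - 1)
                if np.any(lo > hi):
                    clipped += 1
                    continue
                gz = np.exp(-0.5 * ((ax[0][lo[0]:hi[0] + 1] - c[0])
                                    / sigma_vox) ** 2)
                gx = np.exp(-0.5 * ((ax[1][lo[1]:hi[1] + 1] - c[1])
                                    / sigma_vox) ** 2)
                gy = np.exp(-0.5 * ((ax[2][lo[2]:hi[2] + 1] - c[2])
                                    / sigma_vox) ** 2)
                frame[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += \
                    gz[:, None, None] * gx[None, :, None] * gy[None, None, :]
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=shape)
        np.maximum(frame, 0.0, out=frame)
        data[..., t] = frame
    if clipped:
        logger.info("synthesize_volume_stack: clipped %d out-of-grid bubble "
                    "records", clipped)
    return VolumeStack(data, voxel_size=grid.voxel_size,
                       volume_rate=truth.volume_rate,
                       meta={"seed": seed, "psf_fwhm_mm": psf_fwhm_mm,
                             "tissue_amplitude": tissue_amplitude,
                             "noise_sigma": noise_sigma,
                             "clipped_bubbles": clipped})


def rasterize_centerlines(network: VesselNetwork, grid: GridSpec,
                          step_fraction: float = 0.25) -> np.ndarray:
    """Binary voxel raster of all segment centerlines (for symmetry checks)."""
    out = np.zeros(grid.shape, dtype=bool)
    step = step_fraction * grid.voxel_size
    shape = np.array(grid.shape)
    for seg in network.segments:
        n = max(2, int(np.ceil(seg.length / step)) + 1)
        pts = np.linspace(seg.start_point, seg.end_point, n)
        ixf = grid.position_to_index(pts)
        idx = np.round(ixf).astype(int)
        # a point exactly on a voxel boundary (e.g. a vessel on the mirror
        # plane of an even grid) marks both neighbors, keeping the raster
        # reflection-symmetric
        tie = np.abs(ixf - np.floor(ixf) - 0.5) < 1e-9
        cands = [idx]
        for ax in range(3):
            if tie[:, ax].any():
                extra = []
                for c in cands:
                    lo = c.copy(); lo[:, ax] = np.where(
                        tie[:, ax], np.floor(ixf[:, ax]).astype(int),
                        lo[:, ax])
                    hi = c.copy(); hi[:, ax] = np.where(
                        tie[:, ax], np.ceil(ixf[:, ax]).astype(int),
                        hi[:, ax])
                    extra.extend([lo, hi])
                cands = extra
        for c in cands:
            ok = np.all((c >= 0) & (c < shape), axis=1)
            cc = c[ok]
            out[cc[:, 0], cc[:, 1], cc[:, 2]] = True
    return out
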