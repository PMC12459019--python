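"""Hungarian-assignment linking of localizations into tracks, Savitzky–Golay
smoothing, short-track rejection, and per-segment speed computation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import savgol_filter

from .core import DEFAULT_VOLUME_RATE_HZ


@dataclass(frozen=True)
class TrackingConfig:
    """Linking gate and smoothing parameters.

    ``max_link_distance`` gates frame-to-frame assignments; the 0.2 mm
    default corresponds to ~100 mm/s at 500 volumes per second, above any
    expected cerebral flow.  The smoother is a third-order Savitzky–Golay
    filter with a nine-point window, and tracks shorter than ten points are
    discarded.
    """

    max_link_distance: float = 0.2  # mm
    sg_order: int = 3
    sg_window: int = 9              # points, odd
    min_track_points: int = 10

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.min_track_points < self.sg_window:
            raise ValueError("min_track_points must be >= sg_window")
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")


@dataclass
class Track:
    """One microbubble trajectory.

    ``volume_indices`` increase strictly by one (no gap closing);
    ``segment_speeds`` (mm/s, length n−1) are filled by
    :func:`compute_velocities` from the smoothed points.
    """

    volume_indices: np.ndarray            # (n,) ints, consecutive
    points: np.ndarray                    # (n, 3) mm, raw centroids
    smoothed_points: np.ndarray | None = None
    segment_speeds: np.ndarray | None = None
    track_id: int = -1

    @property
    def n_points(self) -> int:
        return len(self.volume_indices)

    def mean_speed(self) -> float:
        if self.segment_speeds is None or len(self.segment_speeds) == 0:
            return float("nan")
        return float(np.mean(self.segment_speeds))


_UNLINKABLE = 1e9  # sentinel cost for gated pairs


def link_tracks(localizations: pd.DataFrame,
                config: TrackingConfig | None = None) -> list[Track]:
    """Link a localization table into raw (unsmoothed) tracks.

    Frame-to-frame assignment minimizes total Euclidean distance subject to
    the ``max_link_distance`` gate (Hungarian algorithm on the rectangular
    cost matrix).  Unmatched detections start new tracks; a track that
    misses one frame terminates and never resumes.
    """
    config = config or TrackingConfig()
    cols = ["z_mm", "x_mm", "y_mm"]
    if len(localizations) == 0:
        return []
    if not localizations["volume_index"].is_monotonic_increasing:
        localizations = localizations.sort_values("volume_index",
                                                  kind="stable",
                                                  ignore_index=True)
    by_vol = {int(t): sub[cols].to_numpy()
              for t, sub in localizations.groupby("volume_index")}
    t_min = min(by_vol)
    t_max = max(by_vol)

    finished: list[Track] = []
    active: list[tuple[list[int], list[np.ndarray]]] = []
    for t in range(t_min, t_max + 1):
        det = by_vol.get(t)
        if det is None or len(det) == 0:
            finished.extend(Track(np.array(vi), np.array(pts))
                            for vi, pts in active)
            active = []
            continue
        next_active: list[tuple[list[int], list[np.ndarray]]] = []
        claimed = np.zeros(len(det), dtype=bool)
        if active:
            last = np.array([pts[-1] for _, pts in active])
            cost = np.linalg.norm(last[:, None, :] - det[None, :, :], axis=2)
            cost = np.where(cost <= config.max_link_distance, cost,
                            _UNLINKABLE)
            rows, cols_idx = linear_sum_assignment(cost)
            matched_tracks = set()
            for r, c in zip(rows, cols_idx):
                if cost[r, c] >= _UNLINKABLE:
                    continue
                vi, pts = active[r]
                vi.append(t)
                pts.append(det[c])
                next_active.append((vi, pts))
                claimed[c] = True
                matched_tracks.add(r)
            for r, (vi, pts) in enumerate(active):
                if r not in matched_tracks:
                    finished.append(Track(np.array(vi), np.array(pts)))
        for c in np.flatnonzero(~claimed):
            next_active.append(([t], [det[c]]))
        active = next_active
    finished.extend(Track(np.array(vi), np.array(pts))
                    for vi, pts in active)
    # deterministic ordering: by start frame, then by first-point coordinates
    finished.sort(key=lambda tr: (int(tr.volume_indices[0]),
                                  tuple(tr.points[0])))
    for i, tr in enumerate(finished):
        tr.track_id = i
    return finished


def smooth_and_filter(tracks: list[Track],
                      config: TrackingConfig | None = None) -> list[Track]:
    """Discard short tracks and smooth the survivors.

    Tracks with fewer than ``min_track_points`` are removed; each coordinate
    of the rest is smoothed independently with the third-order, nine-point
    Savitzky–Golay filter (endpoints by polynomial fit within the window).
    """
    config = config or TrackingConfig()
    kept = [tr for tr in tracks if tr.n_points >= config.min_track_points]
    for tr in kept:
        tr.smoothed_points = savgol_filter(
            tr.points, window_length=config.sg_window,
            polyorder=config.sg_order, axis=0, mode="interp")
    return kept


def compute_velocities(tracks: list[Track],
                       volume_rate: float = DEFAULT_VOLUME_RATE_HZ
                       ) -> list[Track]:
    """Per-segment speed: distance between consecutive smoothed points ×
    volume rate, in mm/s."""
    if volume_rate <= 0:
        raise ValueError("volume_rate must be positive")
    for tr in tracks:
        pts = tr.smoothed_points
        if pts is None:
            raise ValueError("tracks must be smoothed before velocities")
        disp = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        tr.segment_speeds = disp * volume_rate
    return tracks


def track_stack(localizations: pd.DataFrame,
                volume_rate: float = DEFAULT_VOLUME_RATE_HZ,
                config: TrackingConfig | None = None) -> list[Track]:
    """Full chain: link, reject short tracks, smooth, compute speeds."""
    config = config or TrackingConfig()
    tracks = link_tracks(localizations, config)
    tracks = smooth_and_filter(tracks, config)
    return compute_velocities(tracks, volume_rate)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table of tracks (one row per point)."""
    rows = []
    for tr in tracks:
        sm = tr.smoothed_points if tr.smoothed_points is not None \
            else np.full_like(tr.points, np.nan)
        sp = tr.segment_speeds
        for i in range(tr.n_points):
            seg_speed = float(sp[i]) if sp is not None and i < len(sp) \
                else np.nan
            rows.append((tr.track_id, int(tr.volume_indices[i]),
                         *tr.points[i], *sm[i], seg_speed))
    return pd.DataFrame(rows, columns=[
        "track_id", "volume_index", "z_mm", "x_mm", "y_mm",
        "z_smooth_mm", "x_smooth_mm", "y_smooth_mm", "segment_speed_mm_s"])
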