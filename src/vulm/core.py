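"""Core geometry, acquisition constants, and the 4-D volume-stack container.

Coordinate convention used everywhere in this package: arrays are ordered
(depth, lateral, elevation[, time]); positions are in millimetres with voxel
centers at ``(index + 0.5) * voxel_size``; the lateral axis is array axis 1
and bilateral mirroring flips that axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("vulm")

# Acquisition constants of the volumetric imaging scheme this pipeline was
# designed around: a matrix-array transmit at 7.81 MHz, five compounded plane
# waves at a 2500 Hz pulse repetition frequency, beamformed onto a half-
# wavelength isotropic grid.
SOUND_SPEED_M_S: float = 1540.0
CENTER_FREQUENCY_HZ: float = 7.81e6
PULSE_REPETITION_FREQUENCY_HZ: float = 2500.0
N_COMPOUNDING_ANGLES: int = 5
ACQUISITION_SECONDS: float = 200.0
DEFAULT_VOLUME_RATE_HZ: float = 500.0


def wavelength_mm(sound_speed_m_s: float = SOUND_SPEED_M_S,
                  center_frequency_hz: float = CENTER_FREQUENCY_HZ) -> float:
    """Acoustic wavelength λ in millimetres (≈0.1972 mm at the defaults)."""
    return sound_speed_m_s / center_frequency_hz * 1e3


def compounded_volume_rate_hz(
        prf_hz: float = PULSE_REPETITION_FREQUENCY_HZ,
        n_angles: int = N_COMPOUNDING_ANGLES) -> float:
    """Effective volume rate after plane-wave compounding: PRF / #angles."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return prf_hz / n_angles


def total_volumes(acquisition_seconds: float = ACQUISITION_SECONDS,
                  volume_rate_hz: float | None = None) -> int:
    """Number of compounded volumes in one acquisition."""
    if volume_rate_hz is None:
        volume_rate_hz = compounded_volume_rate_hz()
    return int(round(acquisition_seconds * volume_rate_hz))


def dataset_success_rate_pct(n_used: int, n_acquired: int) -> float:
    """Percentage of acquired datasets retained for analysis."""
    if n_acquired <= 0:
        raise ValueError("n_acquired must be positive")
    return 100.0 * n_used / n_acquired


def psf_sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian standard deviation for a given full width at half maximum.

    σ = FWHM / (2 * sqrt(2 ln 2)).  With a bubble point-spread-function FWHM
    of one wavelength on a λ/2 grid (two voxels), σ ≈ 0.85 voxel; the
    localization kernel uses this rounded to 0.8.
    """
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# λ-derived grid steps, in mm.
LAMBDA_MM = wavelength_mm()
BEAMFORM_VOXEL_MM = LAMBDA_MM / 2.0     # ≈ 0.0986 mm
RENDER_VOXEL_MM = LAMBDA_MM / 20.0      # ≈ 0.00986 mm
SYMMETRY_VOXEL_MM = LAMBDA_MM / 5.0     # ≈ 0.0394 mm


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid with origin at 0 mm on every axis."""

    shape: tuple[int, int, int]
    voxel_size: float = BEAMFORM_VOXEL_MM  # mm

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    def position_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a position in mm."""
        return np.asarray(pos_mm, dtype=float) / self.voxel_size - 0.5

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def contains(self, pos_mm: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos_mm, dtype=float))
        ext = self.extent_mm
        return np.all((pos >= 0.0) & (pos < ext), axis=1)


@dataclass
class VolumeStack:
    """4-D beamformed intensity data (depth × lateral × elevation × time)."""

    data: np.ndarray
    voxel_size: float = BEAMFORM_VOXEL_MM   # mm, isotropic
    volume_rate: float = DEFAULT_VOLUME_RATE_HZ  # Hz
    center_frequency: float = CENTER_FREQUENCY_HZ  # Hz
    sound_speed: float = SOUND_SPEED_M_S    # m/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("VolumeStack data must be 4-D (z, x, y, t)")
        if self.voxel_size <= 0 or self.volume_rate <= 0:
            raise ValueError("voxel_size and volume_rate must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(shape=self.data.shape[:3], voxel_size=self.voxel_size)

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed / self.center_frequency * 1e3

    def validate_half_wavelength_grid(self, rtol: float = 0.05) -> bool:
        """True when the declared voxel size is consistent with λ/2."""
        return bool(np.isclose(self.voxel_size, self.wavelength_mm / 2.0,
                               rtol=rtol))
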