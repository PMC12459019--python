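"""Reading and writing of volume stacks, tables, and reports.

Volume stacks go to 4-D NIfTI (voxel size in the affine, volume rate in the
header's time step) or to TIFF with frames stored as (time, depth, lateral,
elevation); tables (networks, ground truth, localizations, tracks) are CSV
with a JSON sidecar carrying grid metadata; metric reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import (CENTER_FREQUENCY_HZ, SOUND_SPEED_M_S, GridSpec,
                   VolumeStack)
from .metrics import MetricsReport


def save_stack_nifti(stack: VolumeStack, path: str | Path) -> None:
    affine = np.diag([stack.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32), affine)
    img.header.set_zooms((stack.voxel_size,) * 3 + (1.0 / stack.volume_rate,))
    nib.save(img, str(path))


def load_stack_nifti(path: str | Path,
                     volume_rate: float | None = None) -> VolumeStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 3:
        data = data[..., None]
    zooms = img.header.get_zooms()
    voxel = float(zooms[0])
    if volume_rate is None:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        volume_rate = 1.0 / dt if dt else 500.0
    return VolumeStack(data, voxel_size=voxel, volume_rate=volume_rate)


def save_stack_tiff(stack: VolumeStack, path: str | Path) -> None:
    """TIFF with axis order (time, depth, lateral, elevation)."""
    tifffile.imwrite(str(path),
                     np.moveaxis(np.asarray(stack.data, dtype=np.float32),
                                 3, 0),
                     metadata={"axes": "TZXY",
                               "voxel_size_mm": stack.voxel_size,
                               "volume_rate_hz": stack.volume_rate})


def load_stack_tiff(path: str | Path, voxel_size: float,
                    volume_rate: float) -> VolumeStack:
    data = np.moveaxis(tifffile.imread(str(path)), 0, 3)
    return VolumeStack(data, voxel_size=voxel_size, volume_rate=volume_rate)


def save_table(df: pd.DataFrame, path: str | Path,
               sidecar: dict | None = None) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar is not None:
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=_jsonify))


def load_table(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    df = pd.read_csv(path)
    sc = path.with_suffix(".json")
    meta = json.loads(sc.read_text()) if sc.exists() else None
    return df, meta


def save_volume_tiff(volume: np.ndarray, path: str | Path,
                     voxel_size: float) -> None:
    tifffile.imwrite(str(path), np.asarray(volume, dtype=np.float32),
                     metadata={"axes": "ZXY", "voxel_size_mm": voxel_size})


def save_metrics_report(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2,
                                     default=_jsonify))


def grid_sidecar(grid: GridSpec, volume_rate: float | None = None) -> dict:
    meta = {"shape": list(grid.shape), "voxel_size_mm": grid.voxel_size,
            "axes": "depth,lateral,elevation",
            "voxel_center_convention": "(index + 0.5) * voxel_size",
            "center_frequency_hz": CENTER_FREQUENCY_HZ,
            "sound_speed_m_s": SOUND_SPEED_M_S}
    if volume_rate is not None:
        meta["volume_rate_hz"] = volume_rate
    return meta


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
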