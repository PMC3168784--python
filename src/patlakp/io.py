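"""File I/O: NIfTI-1 dynamic volumes and maps, timing CSVs, JSON sidecars.

Spatial semantics are delegated entirely to the NIfTI affine; no axis
reorientation is performed.  Maps are written float32; uncompressed
``.nii`` output is byte-deterministic (``.nii.gz`` additionally depends on
nibabel's gzip settings).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .phantom import DynamicImage, F18_HALF_LIFE_MIN, FrameSchedule

__all__ = [
    "read_timing",
    "write_timing",
    "read_dynamic_study",
    "write_dynamic_study",
    "read_mask",
    "write_map",
    "write_parametric_maps",
]


def read_timing(path, units: str = "min",
                half_life_min: float = F18_HALF_LIFE_MIN) -> FrameSchedule:
    """Read a frame-timing CSV with columns ``frame,start_min,duration_min``
    (or ``start_s,duration_s`` with ``units='s'``)."""
    df = pd.read_csv(path)
    suffix = "min" if units == "min" else "s"
    scol, dcol = f"start_{suffix}", f"duration_{suffix}"
    if not {scol, dcol} <= set(df.columns):
        raise FormatError(f"timing CSV needs columns {scol},{dcol}")
    starts = df[scol].to_numpy(float)
    durations = df[dcol].to_numpy(float)
    if units == "s":
        starts, durations = starts / 60.0, durations / 60.0
    elif units != "min":
        raise FormatError(f"unknown timing units {units!r}")
    return FrameSchedule(starts=starts, durations=durations,
                         isotope_half_life=half_life_min)


def write_timing(schedule: FrameSchedule, path) -> None:
    pd.DataFrame({
        "frame": np.arange(schedule.n_frames),
        "start_min": schedule.starts,
        "duration_min": schedule.durations,
    }).to_csv(path, index=False)


def _load_nifti(path):
    try:
        return nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc


def read_dynamic_study(image_path, timing_path, units: str = "min",
                       half_life_min: float = F18_HALF_LIFE_MIN) -> DynamicImage:
    """Load a 4-D NIfTI volume plus its frame-timing CSV as a DynamicImage."""
    img = _load_nifti(image_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D dynamic volume, got {data.ndim}-D")
    schedule = read_timing(timing_path, units=units, half_life_min=half_life_min)
    if data.shape[3] != schedule.n_frames:
        raise FormatError(
            f"image has {data.shape[3]} frames but timing file lists "
            f"{schedule.n_frames}")
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data=data, schedule=schedule,
                        voxel_size_mm=tuple(float(z) for z in zooms),
                        affine=img.affine)


def write_dynamic_study(img: DynamicImage, image_path, timing_path) -> None:
    ni = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    ni.header.set_zooms(tuple(img.voxel_size_mm) + (1.0,))
    nib.save(ni, str(image_path))
    write_timing(img.schedule, timing_path)


def read_mask(path, shape=None) -> np.ndarray:
    m = np.asarray(_load_nifti(path).dataobj)
    if m.ndim != 3:
        raise FormatError("mask must be a 3-D volume")
    if shape is not None and m.shape != tuple(shape):
        raise FormatError(f"mask shape {m.shape} does not match image {tuple(shape)}")
    return m > 0


def write_map(map3d: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), affine), str(path))


def write_parametric_maps(result, prefix, affine=None) -> dict:
    """Write all maps of a fit result with a common filename prefix.

    Works for both the classic-Patlak and the extrapolation results; the
    global lambda and its diagnostics go into a JSON sidecar.  Returns the
    mapping of map name to file path.
    """
    prefix = str(prefix)
    if affine is None:
        affine = np.eye(4)
    written = {}
    if hasattr(result, "ki_map"):  # classic Patlak
        maps = {"ki": result.ki_map, "v": result.v_map, "r2": result.r2_map}
        sidecar = {"t_star": result.t_star,
                   "frames_used": result.frames_used.tolist()}
    else:  # extrapolation fit
        maps = {"pinf": result.pinf_map, "p0": result.p0_map,
                "alpha": result.alpha_map, "r2": result.r2_map}
        sidecar = {"lambda_hat": result.lambda_hat, "t0": result.t0,
                   "roi_fit_diagnostics": result.roi_fit_diagnostics}
    for name, arr in maps.items():
        path = f"{prefix}{name}.nii"
        write_map(arr, affine, path)
        written[name] = path
    side_path = f"{prefix}fit.json"
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["sidecar"] = side_path
    return written
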