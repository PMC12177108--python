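"""File formats and atomic writing.

Series, masks and maps travel as NIfTI with the 2D+t convention
(x, y, t — time as the third axis); a JSON sidecar carries the frame
interval, since NIfTI time units are unreliable across writers. Metrics and
cohort tables are CSV; reports and truth parameters are JSON.

All writers go through a write-to-temp-then-rename helper so partial runs
never leave a valid-looking output file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Callable

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .series import DynamicSeries


def atomic_write(path: str | Path, writer: Callable[[Path], None]) -> Path:
    """Write via a temp file in the target directory, then atomically rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    tmp = Path(tmp)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def write_series(series: DynamicSeries, path: str | Path) -> Path:
    """Save a dynamic series as NIfTI plus a JSON timing sidecar."""
    img = nib.Nifti1Image(series.signal.astype(np.float32), affine=np.eye(4))
    path = atomic_write(path, lambda p: nib.save(img, p))
    sidecar = Path(path).with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    write_json(
        {
            "frame_interval_s": series.frame_interval,
            "n_frames": series.n_frames,
            "pixel_spacing_mm": list(series.pixel_spacing),
        },
        str(sidecar) + ".json",
    )
    return path


def read_series(path: str | Path, frame_interval: float | None = None) -> DynamicSeries:
    """Load a 2D+t NIfTI series; the frame interval comes from the sidecar
    unless given explicitly."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(
            f"expected a 2D+t series with shape (x, y, t); got {data.ndim}D {data.shape} "
            "(multi-slice 3D+t input is unsupported)"
        )
    if frame_interval is None:
        sidecar = Path(str(Path(path).with_suffix("").with_suffix("")) + ".json")
        if sidecar.exists():
            frame_interval = json.loads(sidecar.read_text())["frame_interval_s"]
        else:
            zooms = img.header.get_zooms()
            frame_interval = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 1.0
    times = np.arange(data.shape[2]) * frame_interval
    return DynamicSeries(data, times)


def write_map(arr: np.ndarray, path: str | Path) -> Path:
    """Save a 2D map or mask as NIfTI on the series raster."""
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine=np.eye(4))
    return atomic_write(path, lambda p: nib.save(img, p))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 2:
        raise FormatError(f"expected a 2D mask; got {data.ndim}D {data.shape}")
    return data > 0.5


def write_json(obj: dict, path: str | Path) -> Path:
    return atomic_write(
        path, lambda p: p.write_text(json.dumps(obj, indent=2, default=_json_default))
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    return atomic_write(path, lambda p: df.to_csv(p, index=False))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
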