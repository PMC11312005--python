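"""Image I/O: 16-bit PNG/TIFF round-tripping and DICOM reading.

Images are stored on disk as 16-bit grayscale with the linear mapping
[0, 1] → [0, 65535]; the mapping, pixel spacing and any provenance are
recorded in a JSON sidecar next to the image so a saved image can be
reloaded without loss of metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .grid import ImageGrid

__all__ = ["save_image", "load_image"]

_SCALE_16 = 65535.0
_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(img: ImageGrid, path, metadata: dict | None = None) -> Path:
    """Write a [0, 1] image as 16-bit PNG/TIFF plus a JSON sidecar."""
    path = Path(path)
    values = np.clip(img.values, 0.0, 1.0)
    encoded = np.round(values * _SCALE_16).astype(np.uint16)
    iio.imwrite(path, encoded)
    side = {
        "scale": {"stored_max": int(_SCALE_16), "value_max": 1.0},
        "dx_mm": img.dx,
        "dy_mm": img.dy,
        **img.meta,
        **(metadata or {}),
    }
    _sidecar(path).write_text(json.dumps(side, indent=2, default=str))
    return path


def _load_dicom(path: Path, spacing: float | None, window: tuple[float, float] | None) -> ImageGrid:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"unsupported DICOM pixel data with shape {arr.shape}; need a single slice")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = window if window is not None else (arr.min(), arr.max())
    if hi <= lo:
        raise ValueError("degenerate intensity window")
    values = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        dy, dx = float(ps[0]), float(ps[1])
    elif spacing is not None:
        dx = dy = spacing
    else:
        dx = dy = 0.5
    return ImageGrid(values, dx=dx, dy=dy, meta={"source": str(path)})


def load_image(path, spacing: float | None = None, window: tuple[float, float] | None = None) -> ImageGrid:
    """Load a grayscale PNG/TIFF/DICOM image rescaled to [0, 1].

    Integer PNG/TIFF data are divided by the dtype maximum (255 or 65535);
    DICOM data are rescaled by slope/intercept then min-max normalized over
    ``window`` (or the data range).  Pixel spacing comes from DICOM tags when
    present, else from ``spacing``, else from the sidecar, else 0.5 mm.
    """
    path = Path(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _load_dicom(path, spacing, window)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"unsupported multi-channel image with shape {arr.shape}; need grayscale")
    if np.issubdtype(arr.dtype, np.integer):
        values = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        values = arr.astype(float)
    meta: dict = {"source": str(path)}
    dx = dy = spacing
    side = _sidecar(path)
    if side.exists():
        info = json.loads(side.read_text())
        meta.update(info)
        if spacing is None:
            dx = info.get("dx_mm")
            dy = info.get("dy_mm")
    if dx is None or dy is None:
        dx = dy = 0.5
    return ImageGrid(values, dx=dx, dy=dy, meta=meta)
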