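"""Image-quality metrics: CNR, COV and the normalized noise power spectrum.

Conventions fixed once for the whole package:

* ROI coordinates are 0-based, row-major; an ROI spans the half-open pixel
  ranges ``[row0, row0+height) × [col0, col0+width)``.
* Standard deviations are population standard deviations (divisor ``n``).
* CNR = (S_R − S_BK) / √(σ_R² + σ_BK²) with the sign preserved.
* COV = σ_R / μ_R (lower is less noisy).
* The noise power spectrum of a tile of size N×N with pixel spacing Δx, Δy is
  ``|DFT(tile − trend)|² · Δx·Δy / (N_x·N_y)``, averaged over M tiles; the
  normalized NPS divides by the squared large-area mean signal, giving mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grid import ImageGrid

__all__ = [
    "ROI",
    "ROILayout",
    "ROIStats",
    "NPS2D",
    "NNPSCurve",
    "roi_stats",
    "cnr",
    "cov",
    "nps_2d",
    "radial_average",
    "nnps",
]

_ROLES = ("material", "background", "nnps", "visual")


@dataclass(frozen=True)
class ROI:
    """A labeled rectangular region of interest."""

    row0: int
    col0: int
    height: int
    width: int
    role: str = "material"
    label: str = ""

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError(f"ROI {self.label!r}: height and width must be >= 2")
        if self.role not in _ROLES:
            raise ValueError(f"ROI {self.label!r}: role must be one of {_ROLES}, got {self.role!r}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height), slice(self.col0, self.col0 + self.width))

    def check_inside(self, shape: tuple[int, int]) -> None:
        if (
            self.row0 < 0
            or self.col0 < 0
            or self.row0 + self.height > shape[0]
            or self.col0 + self.width > shape[1]
        ):
            raise ValueError(
                f"ROI {self.label!r} [{self.row0}:{self.row0 + self.height}, "
                f"{self.col0}:{self.col0 + self.width}] lies outside image shape {shape}"
            )

    def extract(self, values: np.ndarray) -> np.ndarray:
        self.check_inside(values.shape)
        return values[self.slices]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("row0", "col0", "height", "width", "role", "label")}


@dataclass
class ROILayout:
    """A set of ROIs plus the material ↔ background pairing map."""

    rois: list[ROI]
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError(f"ROI labels must be unique, got {labels}")
        by_label = {r.label: r for r in self.rois}
        for mat in self.material_labels:
            if mat not in self.pairing:
                raise ValueError(f"material ROI {mat!r} has no paired background ROI")
            bg = self.pairing[mat]
            if bg not in by_label or by_label[bg].role != "background":
                raise ValueError(f"pairing for {mat!r} names {bg!r}, which is not a background ROI")

    @property
    def material_labels(self) -> list[str]:
        return [r.label for r in self.rois if r.role == "material"]

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def background_for(self, material_label: str) -> ROI:
        return self[self.pairing[material_label]]

    def by_role(self, role: str) -> list[ROI]:
        return [r for r in self.rois if r.role == role]

    def validate(self, shape: tuple[int, int]) -> None:
        for r in self.rois:
            r.check_inside(shape)

    def to_dict(self) -> dict:
        return {"rois": [r.to_dict() for r in self.rois], "pairing": dict(self.pairing)}

    @classmethod
    def from_dict(cls, d: dict) -> "ROILayout":
        return cls(rois=[ROI(**r) for r in d["rois"]], pairing=dict(d.get("pairing", {})))


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n: int


def _values(img: ImageGrid | np.ndarray) -> np.ndarray:
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)


def roi_stats(img: ImageGrid | np.ndarray, roi: ROI) -> ROIStats:
    """Mean and population standard deviation over an ROI."""
    patch = roi.extract(_values(img))
    return ROIStats(mean=float(patch.mean()), sd=float(patch.std()), n=patch.size)


def cnr(img: ImageGrid | np.ndarray, material: ROI, background: ROI) -> float:
    """Contrast-to-noise ratio between a material ROI and its background ROI."""
    m = roi_stats(img, material)
    b = roi_stats(img, background)
    denom = np.hypot(m.sd, b.sd)
    if denom == 0:
        raise ValueError(
            f"CNR undefined: both ROIs ({material.label!r}, {background.label!r}) are constant"
        )
    return (m.mean - b.mean) / denom


def cov(img: ImageGrid | np.ndarray, material: ROI) -> float:
    """Coefficient of variation (σ/μ) over an ROI."""
    s = roi_stats(img, material)
    if s.mean == 0:
        raise ValueError(f"COV undefined: ROI {material.label!r} has zero mean")
    return s.sd / s.mean


# -- noise power spectrum ---------------------------------------------------------


@dataclass
class NPS2D:
    """Two-dimensional (possibly normalized) noise power spectrum.

    ``values`` is indexed like ``np.fft.fftfreq`` output (DC at [0, 0]);
    ``fu``/``fv`` are the frequency axes in mm⁻¹.  ``mean_tile_variance`` is
    the average population variance of the detrended tiles, kept for
    Parseval-style checks: ``values.sum() * du * dv == mean_tile_variance``.
    """

    values: np.ndarray
    fu: np.ndarray
    fv: np.ndarray
    roi_count: int
    roi_size: int
    mean_tile_variance: float


@dataclass
class NNPSCurve:
    """Radially binned normalized noise power spectrum (units mm²)."""

    freq: np.ndarray  # radial spatial frequency, mm^-1
    nnps: np.ndarray
    roi_count: int
    roi_size: int


def _tiles(values: np.ndarray, region: ROI, roi_size: int, overlap: float) -> Iterable[np.ndarray]:
    patch = region.extract(values)
    step = max(1, int(round(roi_size * (1.0 - overlap))))
    if patch.shape[0] < roi_size or patch.shape[1] < roi_size:
        raise ValueError(
            f"NNPS region {region.label!r} ({patch.shape}) smaller than one {roi_size}×{roi_size} tile"
        )
    for r in range(0, patch.shape[0] - roi_size + 1, step):
        for c in range(0, patch.shape[1] - roi_size + 1, step):
            yield patch[r : r + roi_size, c : c + roi_size]


def _detrend(tile: np.ndarray, how: str) -> np.ndarray:
    if how == "mean":
        return tile - tile.mean()
    if how == "ramp":  # least-squares planar fit
        n0, n1 = tile.shape
        y, x = np.mgrid[0:n0, 0:n1]
        a = np.column_stack([np.ones(tile.size), x.ravel(), y.ravel()])
        coef, *_ = np.linalg.lstsq(a, tile.ravel(), rcond=None)
        return tile - (a @ coef).reshape(tile.shape)
    raise ValueError(f"unknown detrend {how!r}")


def nps_2d(
    imgs: Sequence[ImageGrid] | ImageGrid,
    region: ROI,
    roi_size: int = 64,
    overlap: float = 0.5,
    detrend: str = "mean",
) -> NPS2D:
    """Ensemble-averaged 2-D noise power spectrum of (half-overlapping) tiles.

    Each tile is detrended (per-tile mean subtraction by default), discrete
    Fourier transformed, and |FT|²·Δx·Δy/(N_x·N_y) is averaged over all
    M tiles drawn from all images.
    """
    if isinstance(imgs, ImageGrid):
        imgs = [imgs]
    if not imgs:
        raise ValueError("need at least one image")
    dx, dy = imgs[0].dx, imgs[0].dy
    for im in imgs:
        if (im.dx, im.dy) != (dx, dy):
            raise ValueError("all images must share the same pixel spacing")
    acc = np.zeros((roi_size, roi_size))
    var_acc = 0.0
    m = 0
    for im in imgs:
        for tile in _tiles(im.values, region, roi_size, overlap):
            t = _detrend(tile, detrend)
            acc += np.abs(np.fft.fft2(t)) ** 2
            var_acc += float(np.mean(t**2))
            m += 1
    acc *= dx * dy / (roi_size * roi_size * m)
    fu = np.fft.fftfreq(roi_size, d=dx)
    fv = np.fft.fftfreq(roi_size, d=dy)
    return NPS2D(
        values=acc,
        fu=fu,
        fv=fv,
        roi_count=m,
        roi_size=roi_size,
        mean_tile_variance=var_acc / m,
    )


def radial_average(nps: NPS2D, n_bins_to_nyquist: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Radially bin a 2-D spectrum into a 1-D curve.

    Bins are ``Nyquist / n_bins_to_nyquist`` wide; samples beyond the Nyquist
    frequency (the square's corners) and the DC sample are excluded.  Returns
    (bin-center frequencies, bin means); empty bins are dropped.
    """
    r = np.hypot(nps.fu[:, None], nps.fv[None, :])
    nyq = min(np.abs(nps.fu).max(), np.abs(nps.fv).max())
    width = nyq / n_bins_to_nyquist
    mask = np.ones_like(r, dtype=bool)
    mask[0, 0] = False  # DC excluded
    mask &= r <= nyq + 1e-12
    idx = np.minimum((r[mask] / width).astype(int), n_bins_to_nyquist - 1)
    vals = nps.values[mask]
    sums = np.bincount(idx, weights=vals, minlength=n_bins_to_nyquist)
    counts = np.bincount(idx, minlength=n_bins_to_nyquist)
    keep = counts > 0
    centers = (np.arange(n_bins_to_nyquist) + 0.5) * width
    return centers[keep], sums[keep] / counts[keep]


def nnps(
    imgs: Sequence[ImageGrid] | ImageGrid,
    region: ROI,
    roi_size: int = 64,
    overlap: float = 0.5,
    detrend: str = "mean",
    norm_reference: float | None = None,
    reference_image: ImageGrid | None = None,
    min_reference: float = 0.01,
) -> NNPSCurve:
    """Normalized noise power spectrum over an air region, radially binned.

    The NPS is divided by the squared large-area mean signal.  The reference
    mean is, in order of precedence: ``norm_reference`` if given; the mean of
    ``reference_image`` (the noiseless scan) over the region; else the
    ensemble mean of the inputs over the region.  A reference mean below
    ``min_reference`` (air is nominally zero) is rejected because dividing
    by its square would explode — supply the large-area signal of a bulk
    region instead.
    """
    if isinstance(imgs, ImageGrid):
        imgs = [imgs]
    spectrum = nps_2d(imgs, region, roi_size=roi_size, overlap=overlap, detrend=detrend)
    if norm_reference is None:
        src = reference_image.values if reference_image is not None else None
        if src is not None:
            norm_reference = float(region.extract(src).mean())
        else:
            norm_reference = float(np.mean([region.extract(im.values).mean() for im in imgs]))
    if abs(norm_reference) < min_reference:
        raise ValueError(
            f"large-area reference signal {norm_reference!r} too small to normalize by; "
            "pass norm_reference explicitly (e.g. the phantom bulk mean)"
        )
    spectrum.values = spectrum.values / norm_reference**2
    freq, vals = radial_average(spectrum)
    return NNPSCurve(freq=freq, nnps=vals, roi_count=spectrum.roi_count, roi_size=roi_size)
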