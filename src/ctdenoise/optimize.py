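"""Smoothing-factor optimization by the half-slope rule.

The FNLM smoothing factor d is swept over a fixed grid (0.01 … 1.00, step
0.01 by default); at each d the denoised image is scored with CNR (per
material/background ROI pair) and COV (per material ROI), giving one metric
curve per tissue region.  Both metrics change steeply at small d and then
saturate.  The selection rule takes, per curve, the smallest d at which the
magnitude of the (smoothed, finite-difference) slope has fallen to half its
maximum and stays there; the per-metric factor is the mean over the three
tissue regions, and the final optimized factor is the two-decimal rounded
mean of the CNR- and COV-derived factors.

Because non-local means output at a pixel depends only on pixels within
``patch_radius + search_radius`` of it, the sweep by default denoises only
ROI-sized crops padded by that margin — bit-identical to denoising the full
image, at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .denoise import FastNLMeansDenoiser
from .grid import ImageGrid
from .metrics import ROI, ROILayout, roi_stats

__all__ = [
    "MetricCurve",
    "OptimizationResult",
    "NoHalfSlopeError",
    "default_d_grid",
    "sweep_smoothing_factor",
    "half_slope_factor",
    "combine_factors",
    "SmoothingFactorOptimizer",
]


class NoHalfSlopeError(ValueError):
    """Raised when a metric curve's slope never falls to half its maximum."""


def default_d_grid() -> np.ndarray:
    """The standard sweep grid: 0.01 to 1.00 in steps of 0.01."""
    return np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class MetricCurve:
    """A metric (CNR or COV) as a function of the smoothing factor d."""

    d_grid: np.ndarray
    values: np.ndarray
    metric: str  # "CNR" | "COV"
    region: str  # tissue label, e.g. CSF / GM / WM
    noise_intensity: float | None = None

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.d_grid.ndim != 1 or self.d_grid.shape != self.values.shape:
            raise ValueError("d_grid and values must be 1-D and of equal length")
        if len(self.d_grid) > 1 and not np.all(np.diff(self.d_grid) > 0):
            raise ValueError("d_grid must be strictly increasing")


@dataclass(frozen=True)
class OptimizationResult:
    """Optimized smoothing factors for one noise intensity."""

    noise_intensity: float
    d_cnr: float  # region-averaged half-slope factor of the CNR curves
    d_cov: float  # region-averaged half-slope factor of the COV curves
    d_opt: float  # rounded mean of d_cnr and d_cov


def _crop_with_margin(values: np.ndarray, roi: ROI, margin: int):
    r0, c0 = roi.row0 - margin, roi.col0 - margin
    r1, c1 = roi.row0 + roi.height + margin, roi.col0 + roi.width + margin
    if r0 < 0 or c0 < 0 or r1 > values.shape[0] or c1 > values.shape[1]:
        return None
    return values[r0:r1, c0:c1]


def _roi_interior(crop_denoised: np.ndarray, margin: int) -> np.ndarray:
    return crop_denoised[margin:-margin, margin:-margin]


def sweep_smoothing_factor(
    noisy: ImageGrid | Sequence[ImageGrid],
    layout: ROILayout,
    denoiser: FastNLMeansDenoiser | None = None,
    d_grid: np.ndarray | None = None,
    restrict_to_rois: bool = True,
) -> list[MetricCurve]:
    """Compute CNR and COV curves over the d grid for every material region.

    ``noisy`` may be a single image or a list of noise realizations, in which
    case the curves are replicate means.  Returns 2 metrics × (number of
    material ROIs) curves.
    """
    if isinstance(noisy, ImageGrid):
        noisy = [noisy]
    if not noisy:
        raise ValueError("need at least one noisy image")
    denoiser = denoiser if denoiser is not None else FastNLMeansDenoiser()
    d_grid = default_d_grid() if d_grid is None else np.asarray(d_grid, dtype=float)
    if d_grid.size == 0 or (d_grid.size > 1 and not np.all(np.diff(d_grid) > 0)):
        raise ValueError("d_grid must be non-empty and strictly increasing")
    materials = layout.material_labels
    margin = denoiser.patch_radius + denoiser.search_radius
    noise_v = noisy[0].meta.get("noise_intensity")

    cnr_acc = np.zeros((len(materials), d_grid.size))
    cov_acc = np.zeros((len(materials), d_grid.size))
    for img in noisy:
        layout.validate(img.shape)
        engines = {}
        use_crops = restrict_to_rois
        if restrict_to_rois:
            for mat in materials:
                for roi in (layout[mat], layout.background_for(mat)):
                    crop = _crop_with_margin(img.values, roi, margin)
                    if crop is None:  # ROI too close to the border: fall back
                        use_crops = False
                        break
                    engines[roi.label] = denoiser.sweep_engine(crop)
                if not use_crops:
                    break
        full_engine = None if use_crops else denoiser.sweep_engine(img.values)
        for k, d in enumerate(d_grid):
            if use_crops:
                stats = {}
                for label, e in engines.items():
                    interior = _roi_interior(e.denoise(d), margin)
                    stats[label] = (interior.mean(), interior.std())
            else:
                den = full_engine.denoise(d)
                stats = {}
                for mat in materials:
                    for roi in (layout[mat], layout.background_for(mat)):
                        s = roi_stats(den, roi)
                        stats[roi.label] = (s.mean, s.sd)
            for i, mat in enumerate(materials):
                sm, sd = stats[mat]
                bm, bd = stats[layout.pairing[mat]]
                denom = float(np.hypot(sd, bd))
                if denom == 0:
                    raise ValueError(f"CNR denominator vanished for region {mat!r} at d={d}")
                cnr_acc[i, k] += (sm - bm) / denom
                if sm == 0:
                    raise ValueError(f"COV undefined (zero mean) for region {mat!r} at d={d}")
                cov_acc[i, k] += sd / sm

    cnr_acc /= len(noisy)
    cov_acc /= len(noisy)
    curves = []
    for i, mat in enumerate(materials):
        curves.append(MetricCurve(d_grid, cnr_acc[i], "CNR", mat, noise_v))
        curves.append(MetricCurve(d_grid, cov_acc[i], "COV", mat, noise_v))
    return curves


def _slope_magnitude(values: np.ndarray, d_grid: np.ndarray, window: int) -> np.ndarray:
    """|dy/dd| via a centered Savitzky–Golay derivative (central differences
    are its window-3 special case; window 1 disables smoothing)."""
    h = float(d_grid[1] - d_grid[0])
    n = len(values)
    w = min(window, n if n % 2 == 1 else n - 1)
    if w < 5 or not np.allclose(np.diff(d_grid), h):
        return np.abs(np.gradient(values, d_grid))
    from scipy.signal import savgol_filter

    return np.abs(savgol_filter(values, w, polyorder=2, deriv=1, delta=h))


def half_slope_factor(curve: MetricCurve, smooth_window: int = 13) -> float:
    """Smallest d at which the curve's slope magnitude persistently halves.

    The slope magnitude is estimated with a centered quadratic
    Savitzky–Golay derivative filter of width ``smooth_window`` (window 1
    falls back to plain central differences).  Metric-versus-d curves rise
    (CNR) or fall (COV) steeply and then saturate, so |slope| is monotone
    decreasing beyond its peak; a decreasing isotonic regression is fitted
    from the peak onward, which denoises the slope while making the
    "stays at or below half the reference" condition exact.  The reference
    slope is the fitted peak value; the crossing of the half-reference level
    is located by linear interpolation on the fit and snapped to the nearest
    grid point.

    Note the reference is the maximum *observable* slope: for a curve
    sampled from d₀ = 0.01 the analytic half-slope point of
    y = 1 − exp(−d/L) is d₀ + L·ln 2 (relative to the slope at d₀), not
    L·ln 2.  Localization error is bounded by about half the derivative
    window when the slope changes discontinuously.

    Raises
    ------
    NoHalfSlopeError
        If no such point exists (e.g. an exactly linear curve, or a curve
        still steepening at the end of the grid).
    """
    if len(curve.d_grid) < 5:
        raise ValueError("curve must have at least 5 points")
    from sklearn.isotonic import IsotonicRegression

    slope = _slope_magnitude(curve.values, curve.d_grid, smooth_window)
    i0 = int(slope.argmax())
    g = curve.d_grid[i0:]
    fitted = IsotonicRegression(increasing=False).fit(g, slope[i0:]).predict(g)
    s_ref = fitted[0]
    thr = s_ref / 2
    below = fitted <= thr + 1e-15
    if not below.any():
        raise NoHalfSlopeError(
            f"slope of the {curve.metric}/{curve.region} curve never falls to half its maximum"
        )
    j = int(np.argmax(below))
    if j == 0:
        d_star = g[0]
    else:
        f0, f1 = fitted[j - 1], fitted[j]
        t = 0.5 if f0 == f1 else (f0 - thr) / (f0 - f1)
        d_star = g[j - 1] + t * (g[j] - g[j - 1])
    return float(curve.d_grid[int(np.argmin(np.abs(curve.d_grid - d_star)))])


def combine_factors(d_cnr: float, d_cov: float) -> float:
    """Arithmetic mean of the two per-metric factors, rounded to 2 decimals.

    Rounding is decimal half-away-from-zero (so 0.245 → 0.25).
    """
    for name, v in (("d_cnr", d_cnr), ("d_cov", d_cov)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    q = Decimal("1e-9")
    a = Decimal(repr(float(d_cnr))).quantize(q, rounding=ROUND_HALF_UP)
    b = Decimal(repr(float(d_cov))).quantize(q, rounding=ROUND_HALF_UP)
    mean = (a + b) / 2
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class SmoothingFactorOptimizer:
    """Estimator deriving the optimized FNLM smoothing factor from noisy images.

    ``fit(X, layout)`` sweeps d over ``d_grid`` on the noisy image(s) X,
    builds per-region CNR and COV curves, applies the half-slope rule per
    curve, averages over regions per metric, and combines the two factors.

    Fitted attributes
    -----------------
    curves_ : list of MetricCurve
    d_cnr_, d_cov_ : float, region-averaged per-metric half-slope factors
    d_opt_ : float, the combined optimized smoothing factor
    result_ : OptimizationResult
    """

    def __init__(
        self,
        denoiser: FastNLMeansDenoiser | None = None,
        d_grid: np.ndarray | None = None,
        smooth_window: int = 13,
        restrict_to_rois: bool = True,
    ):
        self.denoiser = denoiser
        self.d_grid = d_grid
        self.smooth_window = smooth_window
        self.restrict_to_rois = restrict_to_rois

    def get_params(self, deep: bool = True) -> dict:
        return {
            "denoiser": self.denoiser,
            "d_grid": self.d_grid,
            "smooth_window": self.smooth_window,
            "restrict_to_rois": self.restrict_to_rois,
        }

    def set_params(self, **params) -> "SmoothingFactorOptimizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: ImageGrid | Sequence[ImageGrid], layout: ROILayout) -> "SmoothingFactorOptimizer":
        self.curves_ = sweep_smoothing_factor(
            X, layout, denoiser=self.denoiser, d_grid=self.d_grid, restrict_to_rois=self.restrict_to_rois
        )
        per_metric = {}
        for metric in ("CNR", "COV"):
            factors = [
                half_slope_factor(c, self.smooth_window) for c in self.curves_ if c.metric == metric
            ]
            per_metric[metric] = float(np.mean(factors))
        self.d_cnr_ = per_metric["CNR"]
        self.d_cov_ = per_metric["COV"]
        self.d_opt_ = combine_factors(self.d_cnr_, self.d_cov_)
        v = self.curves_[0].noise_intensity
        self.result_ = OptimizationResult(
            noise_intensity=float("nan") if v is None else v,
            d_cnr=self.d_cnr_,
            d_cov=self.d_cov_,
            d_opt=self.d_opt_,
        )
        return self
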