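"""Denoising algorithms: fast non-local means plus classical comparators.

Non-local means (NLM) replaces each pixel value I(m) by a weighted average of
the pixels n in a search window around m,

    NL[I](m) = Σ_n ω(m, n) · I(n),
    ω(m, n)  = exp(−D(m, n) / d²) / Z(m),
    D(m, n)  = Σ_τ G_σ(τ) · (I(m + τ) − I(n + τ))²,

where τ ranges over the patch offsets, G_σ is an (unnormalized, peak-1)
Gaussian weighting of the patch, d is the smoothing factor, and Z(m)
normalizes the weights to sum to one.  The *fast* NLM (FNLM) computes the
same weights by decomposing the patch sum D into one-dimensional running
sums: for each candidate translation τ the shifted squared-difference image
is built once and integrated over the patch support with cumulative tables
along each axis, so the per-pixel cost is independent of the patch size.
Both paths use symmetric (mirror) boundary padding and are numerically
equivalent; the brute-force path exists as the independent oracle.

Comparators: a normalized Gaussian convolution, an adaptive local Wiener
filter, and Rudin–Osher–Fatemi total-variation denoising.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import ImageGrid

__all__ = [
    "FastNLMeansDenoiser",
    "GaussianDenoiser",
    "WienerDenoiser",
    "TVDenoiser",
    "fnlm_denoise",
    "nlm_brute_force",
    "gaussian_denoise",
    "wiener_denoise",
    "tv_denoise",
]


def _unwrap(X):
    if isinstance(X, ImageGrid):
        return X.values, X.with_values
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return arr, (lambda v: v)


# -- NLM / FNLM machinery ---------------------------------------------------------


def _check_nlm_params(d, patch_radius, search_radius):
    if not d > 0:
        raise ValueError(f"smoothing factor d must be > 0, got {d}")
    if patch_radius < 0:
        raise ValueError(f"patch_radius must be >= 0, got {patch_radius}")
    if search_radius < 1:
        raise ValueError(f"search_radius must be >= 1, got {search_radius}")


def _resolve_sigma(patch_kernel_sigma, patch_radius):
    if patch_kernel_sigma == "auto":
        return patch_radius / 2 if patch_radius > 0 else None
    return patch_kernel_sigma  # None means a uniform patch window


def _patch_kernel_1d(patch_radius: int, sigma: float | None) -> np.ndarray:
    """Separable 1-D factor of the patch weighting G_σ.

    The 2-D kernel (the outer product of this factor with itself) sums to 1,
    so the patch distance is a Gaussian-weighted *average* squared difference
    — the standard non-local-means convention, which keeps the useful range
    of the smoothing factor d comparable across patch sizes.
    """
    offs = np.arange(-patch_radius, patch_radius + 1, dtype=float)
    if sigma is None:
        k = np.ones_like(offs)
    else:
        if sigma <= 0:
            raise ValueError(f"patch_kernel_sigma must be positive, got {sigma}")
        k = np.exp(-(offs**2) / (2.0 * sigma**2))
    return k / k.sum()


def _check_image_size(shape, patch_radius, search_radius):
    need = 2 * (patch_radius + search_radius)
    if min(shape) <= need:
        raise ValueError(
            f"image sides must exceed 2·(patch_radius + search_radius) = {need}, got {shape}"
        )


def _running_sum_axis(ext: np.ndarray, radius: int, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Integrate ``ext`` over the patch support along one axis.

    ``ext`` extends the target range by ``radius`` samples on both ends of
    ``axis``.  For the uniform kernel the window sums come from differences
    of a cumulative table, H(m + s) − H(m − s − 1); a Gaussian kernel uses a
    1-D correlation with the same alignment.  Either way the work per output
    sample along this axis is independent of the patch size times a constant.
    """
    if radius == 0:
        return ext
    if np.ptp(kernel) == 0:  # uniform window: exact cumulative-table differences
        c = np.cumsum(ext * kernel[0], axis=axis)
        zeros_shape = list(ext.shape)
        zeros_shape[axis] = 1
        c = np.concatenate([np.zeros(zeros_shape), c], axis=axis)
        n_out = ext.shape[axis] - 2 * radius
        hi = [slice(None)] * ext.ndim
        lo = [slice(None)] * ext.ndim
        hi[axis] = slice(2 * radius + 1, 2 * radius + 1 + n_out)
        lo[axis] = slice(0, n_out)
        return c[tuple(hi)] - c[tuple(lo)]
    full = ndimage.correlate1d(ext, kernel, axis=axis, mode="constant")
    sl = [slice(None)] * ext.ndim
    sl[axis] = slice(radius, ext.shape[axis] - radius)
    return full[tuple(sl)]


def _offsets(search_radius: int):
    for dr in range(-search_radius, search_radius + 1):
        for dc in range(-search_radius, search_radius + 1):
            if dr == 0 and dc == 0:
                continue
            yield dr, dc


def _shifted_patch_distances(values: np.ndarray, patch_radius: int, search_radius: int, kernel1d: np.ndarray):
    """Yield (dist², shifted-intensity) pairs for every search-window offset.

    ``dist²`` has the image's shape; entry m holds the Gaussian-weighted
    squared patch distance between the patches at m and m + τ.
    """
    h, w = values.shape
    p, r = patch_radius, search_radius
    pad = p + r
    padded = np.pad(values, pad, mode="symmetric")
    a = padded[pad - p : pad + p + h, pad - p : pad + p + w]
    for dr, dc in _offsets(r):
        b = padded[pad - p + dr : pad + p + h + dr, pad - p + dc : pad + p + w + dc]
        diff2 = (a - b) ** 2
        dist = _running_sum_axis(diff2, p, kernel1d, axis=0)
        dist = _running_sum_axis(dist, p, kernel1d, axis=1)
        shifted = padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
        yield dist, shifted


def _fnlm_core(values, d, patch_radius, search_radius, sigma, self_weight):
    kernel = _patch_kernel_1d(patch_radius, sigma)
    pairs = list(_shifted_patch_distances(values, patch_radius, search_radius, kernel))
    # Weights are normalized per pixel, so rescaling them all by exp(dmin/d²)
    # is exact; it prevents every weight underflowing to zero at small d.
    # With the "max" self-weight rule the center weight equals the rescaled
    # maximum, i.e. exactly 1; with the literal rule exp(0)=1 already
    # dominates, so no shift is applied.
    shift = np.min([dist for dist, _ in pairs], axis=0) if self_weight == "max" else 0.0
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    inv = 1.0 / d**2
    for dist, shifted in pairs:
        w = np.exp(-(dist - shift) * inv)
        num += w * shifted
        den += w
    wc = np.ones_like(values)
    return (num + wc * values) / (den + wc)


class _FNLMSweepEngine:
    """Reusable FNLM evaluator for sweeping d on a fixed image.

    The per-offset patch-distance tables do not depend on the smoothing
    factor, so they are computed once and only the exponential weighting is
    redone per d.  Output is identical to :func:`fnlm_denoise`.
    """

    def __init__(self, values, patch_radius=2, search_radius=5, patch_kernel_sigma="auto", self_weight="max"):
        _check_nlm_params(1.0, patch_radius, search_radius)
        _check_image_size(values.shape, patch_radius, search_radius)
        sigma = _resolve_sigma(patch_kernel_sigma, patch_radius)
        kernel = _patch_kernel_1d(patch_radius, sigma)
        pairs = list(_shifted_patch_distances(values, patch_radius, search_radius, kernel))
        self.values = values
        self.self_weight = self_weight
        self.dist = np.stack([p[0] for p in pairs])
        self.shifted = np.stack([p[1] for p in pairs])
        # same stabilizing shift as _fnlm_core (exact: weights are normalized)
        self.shift = self.dist.min(axis=0) if self_weight == "max" else 0.0

    def denoise(self, d: float) -> np.ndarray:
        w = np.exp(-(self.dist - self.shift) / d**2)
        num = np.einsum("kij,kij->ij", w, self.shifted)
        den = w.sum(axis=0)
        return (num + self.values) / (den + 1.0)


# -- estimators -------------------------------------------------------------------


class _ImageDenoiser(TransformerMixin, BaseEstimator):
    """Base class: stateless image-to-image transformers over 2-D arrays.

    ``transform`` accepts an :class:`~ctdenoise.grid.ImageGrid` or a bare
    2-D array and returns the same type.  ``fit`` only validates parameters.
    """

    def fit(self, X=None, y=None):
        self._validate_params_()
        self.is_fitted_ = True
        return self

    def transform(self, X):
        self._validate_params_()
        values, wrap = _unwrap(X)
        return wrap(self._denoise(values))

    def _validate_params_(self):  # pragma: no cover - overridden
        pass


class FastNLMeansDenoiser(_ImageDenoiser):
    """Fast non-local means denoiser.

    Parameters
    ----------
    d : float
        Smoothing factor dividing the patch distance inside the exponential
        weight; larger d smooths more.
    patch_radius : int
        Half-width of the similarity patch (default 2, i.e. 5×5 patches).
    search_radius : int
        Half-width of the candidate search window (default 5, i.e. 11×11).
    patch_kernel_sigma : "auto", float or None
        σ of the Gaussian patch weighting; "auto" uses patch_radius / 2,
        ``None`` selects a uniform patch window.
    self_weight : {"max", "one"}
        Weight of the center pixel: the maximum of its neighbours' weights
        (standard practice, avoids self-dominance) or the literal exp(0) = 1.
    """

    def __init__(self, d=0.2, patch_radius=2, search_radius=5, patch_kernel_sigma="auto", self_weight="max"):
        self.d = d
        self.patch_radius = patch_radius
        self.search_radius = search_radius
        self.patch_kernel_sigma = patch_kernel_sigma
        self.self_weight = self_weight

    def _validate_params_(self):
        _check_nlm_params(self.d, self.patch_radius, self.search_radius)
        if self.self_weight not in ("max", "one"):
            raise ValueError(f"self_weight must be 'max' or 'one', got {self.self_weight!r}")

    def _denoise(self, values):
        _check_image_size(values.shape, self.patch_radius, self.search_radius)
        sigma = _resolve_sigma(self.patch_kernel_sigma, self.patch_radius)
        return _fnlm_core(values, self.d, self.patch_radius, self.search_radius, sigma, self.self_weight)

    def sweep_engine(self, X) -> _FNLMSweepEngine:
        """Precompute distance tables on X for repeated evaluation at many d."""
        self._validate_params_()
        values, _ = _unwrap(X)
        return _FNLMSweepEngine(
            values, self.patch_radius, self.search_radius, self.patch_kernel_sigma, self.self_weight
        )


class GaussianDenoiser(_ImageDenoiser):
    """Convolution with a normalized 2-D Gaussian kernel (DC gain exactly 1)."""

    def __init__(self, sigma=1.0, truncate=4.0):
        self.sigma = sigma
        self.truncate = truncate

    def _validate_params_(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def _denoise(self, values):
        return ndimage.gaussian_filter(values, self.sigma, mode="reflect", truncate=self.truncate)


class WienerDenoiser(_ImageDenoiser):
    """Adaptive local Wiener filter.

    out = μ_loc + max(σ²_loc − σ²_noise, 0) / max(σ²_loc, σ²_noise) · (in − μ_loc)

    with local moments over an odd ``window`` (symmetric padding).  When
    ``noise_variance`` is not supplied it is estimated as the mean of the
    local variances.
    """

    def __init__(self, window=5, noise_variance=None):
        self.window = window
        self.noise_variance = noise_variance

    def _validate_params_(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")

    def _denoise(self, values):
        mu = ndimage.uniform_filter(values, self.window, mode="reflect")
        m2 = ndimage.uniform_filter(values * values, self.window, mode="reflect")
        var = np.maximum(m2 - mu * mu, 0.0)
        nv = self.noise_variance if self.noise_variance is not None else float(var.mean())
        denom = np.maximum(var, nv)
        gain = np.divide(np.maximum(var - nv, 0.0), denom, out=np.zeros_like(var), where=denom > 0)
        return mu + gain * (values - mu)


class TVDenoiser(_ImageDenoiser):
    """Rudin–Osher–Fatemi total-variation denoising (Chambolle dual projection).

    Minimizes ‖u − f‖²/2 + weight·TV(u); stops after ``max_iter`` iterations
    or when the relative change falls below ``tol``.
    """

    def __init__(self, weight=0.1, max_iter=200, tol=1e-5):
        self.weight = weight
        self.max_iter = max_iter
        self.tol = tol

    def _validate_params_(self):
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")

    def _denoise(self, values):
        if self.weight == 0:
            return values.copy()
        return denoise_tv_chambolle(
            values, weight=self.weight, eps=self.tol, max_num_iter=self.max_iter
        )


# -- brute-force NLM oracle -------------------------------------------------------


def nlm_brute_force(
    img,
    d=0.2,
    patch_radius=2,
    search_radius=5,
    patch_kernel_sigma="auto",
    self_weight="max",
    return_weights=False,
):
    """Direct per-pixel non-local means, the oracle the fast path must match.

    Loops over every pixel and every candidate in its search window, summing
    Gaussian-weighted squared patch differences explicitly.  With
    ``return_weights=True`` also returns the normalized weight tensor of
    shape (ny, nx, 2R+1, 2R+1) — weights over each pixel's search window,
    center included — whose per-pixel sums are exactly 1.
    """
    _check_nlm_params(d, patch_radius, search_radius)
    values, wrap = _unwrap(img)
    _check_image_size(values.shape, patch_radius, search_radius)
    sigma = _resolve_sigma(patch_kernel_sigma, patch_radius)
    k1 = _patch_kernel_1d(patch_radius, sigma)
    kernel2d = np.outer(k1, k1)
    h, w = values.shape
    p, r = patch_radius, search_radius
    pad = p + r
    padded = np.pad(values, pad, mode="symmetric")
    out = np.empty_like(values)
    weights = np.zeros((h, w, 2 * r + 1, 2 * r + 1)) if return_weights else None
    for i in range(h):
        for j in range(w):
            ci, cj = i + pad, j + pad
            ref = padded[ci - p : ci + p + 1, cj - p : cj + p + 1]
            dists = np.empty((2 * r + 1, 2 * r + 1))
            for dr in range(-r, r + 1):
                for dc in range(-r, r + 1):
                    ni, nj = ci + dr, cj + dc
                    cand = padded[ni - p : ni + p + 1, nj - p : nj + p + 1]
                    dists[dr + r, dc + r] = np.sum(kernel2d * (ref - cand) ** 2)
            # stabilizing shift, exact under weight normalization (see _fnlm_core)
            center = (r, r)
            mask = np.ones_like(dists, dtype=bool)
            mask[center] = False
            shift = dists[mask].min() if self_weight == "max" else 0.0
            dists[center] = shift  # placeholder; center weight is set explicitly below
            wtab = np.exp(-(dists - shift) / d**2)
            wtab[center] = 1.0  # max-of-neighbours rule (or literal exp(0))
            z = wtab.sum()
            neighbor_vals = padded[ci - r : ci + r + 1, cj - r : cj + r + 1].copy()
            neighbor_vals[center] = values[i, j]
            out[i, j] = float(np.sum(wtab * neighbor_vals)) / z
            if return_weights:
                weights[i, j] = wtab / z
    result = wrap(out)
    return (result, weights) if return_weights else result


# -- thin function wrappers -------------------------------------------------------


def fnlm_denoise(img, d=0.2, patch_radius=2, search_radius=5, patch_kernel_sigma="auto", self_weight="max"):
    """Fast non-local means denoising (see :class:`FastNLMeansDenoiser`)."""
    est = FastNLMeansDenoiser(
        d=d,
        patch_radius=patch_radius,
        search_radius=search_radius,
        patch_kernel_sigma=patch_kernel_sigma,
        self_weight=self_weight,
    )
    return est.fit().transform(img)


def gaussian_denoise(img, sigma=1.0):
    return GaussianDenoiser(sigma=sigma).fit().transform(img)


def wiener_denoise(img, window=5, noise_variance=None):
    return WienerDenoiser(window=window, noise_variance=noise_variance).fit().transform(img)


def tv_denoise(img, weight=0.1, max_iter=200, tol=1e-5):
    return TVDenoiser(weight=weight, max_iter=max_iter, tol=tol).fit().transform(img)
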