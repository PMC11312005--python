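"""2-D image container with physical pixel spacing.

All intensities in this package are dimensionless attenuation-like values on a
nominal [0, 1] scale; spatial frequencies derived from an :class:`ImageGrid`
are therefore in cycles/mm and noise-power spectra in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A real-valued 2-D image with pixel spacing in millimetres.

    Parameters
    ----------
    values : ndarray of shape (ny, nx)
        Pixel intensities, row-major (row 0 is the top of the image).
    dx, dy : float
        Pixel spacing along the x (column) and y (row) axes, mm.
    """

    values: np.ndarray
    dx: float = 0.5
    dy: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("image must contain at least one pixel per side")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"pixel spacing must be positive, got dx={self.dx}, dy={self.dy}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def ny(self) -> int:
        """Number of rows (N_y)."""
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        """Number of columns (N_x)."""
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """Return a copy of this grid carrying ``values`` (spacing preserved)."""
        return replace(self, values=np.asarray(values, dtype=float), meta=dict(self.meta))

    def copy(self) -> "ImageGrid":
        return self.with_values(self.values.copy())
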