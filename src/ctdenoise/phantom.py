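"""Digital replica of a 3D-printed cylindrical brain phantom.

The physical object being emulated is a 16 cm printed case (a skull-sized
cylinder of water-like plastic) holding five 2.5 cm cylindrical inserts whose
linear attenuation coefficients mimic cerebrospinal fluid (XT-CF20,
0.208 cm⁻¹), gray matter (wood, 0.213 cm⁻¹), white matter (ABS, 0.214 cm⁻¹),
air, and bone (bronze, 0.839 cm⁻¹).  A single axial slice through the inserts
is rasterized on a square pixel grid; pixel intensities equal μ in cm⁻¹
(all below 1, so the nominal [0, 1] display scale needs no rescaling).

Low-dose acquisitions are emulated by adding zero-mean Gaussian noise to the
clean slice.  The noise "intensity" follows the MATLAB ``imnoise`` convention:
it is the noise *variance* on the [0, 1]-scaled image, and the result is
clamped back to [0, 1].  Both choices can be overridden via
:class:`NoiseSpec` (``mode="std"``, ``clip=False``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid
from .metrics import ROI, ROILayout

__all__ = [
    "MaterialDef",
    "Insert",
    "PhantomSpec",
    "NoiseSpec",
    "PhantomGeometryError",
    "ROILayoutError",
    "generate_phantom",
    "add_gaussian_noise",
    "default_roi_layout",
    "TABLE_MATERIALS",
]


class PhantomGeometryError(ValueError):
    """Raised when a phantom specification violates its geometric invariants."""


class ROILayoutError(ValueError):
    """Raised when a requested ROI layout cannot be placed on the phantom."""


@dataclass(frozen=True)
class MaterialDef:
    """A filament material with its measured linear attenuation coefficient.

    ``mimics`` names the reference tissue the filament stands in for
    (CSF, GM, WM, bone, air) or ``None`` for structural materials.
    """

    name: str
    mu: float  # linear attenuation coefficient, cm^-1
    mimics: str | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"material {self.name!r}: mu must be >= 0, got {self.mu}")


#: Filament materials of the printed phantom and the tissues they mimic.
TABLE_MATERIALS: dict[str, MaterialDef] = {
    "XT-CF20": MaterialDef("XT-CF20", 0.208, "CSF"),
    "wood": MaterialDef("wood", 0.213, "GM"),
    "air": MaterialDef("air", 0.0, "air"),
    "ABS": MaterialDef("ABS", 0.214, "WM"),
    "bronze": MaterialDef("bronze", 0.839, "bone"),
}


@dataclass(frozen=True)
class Insert:
    """A cylindrical insert: material, center offset from image center (mm), diameter (mm).

    The offset is (x, y) with x pointing right and y pointing up.
    """

    material: MaterialDef
    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 25.0


def _default_inserts() -> list[Insert]:
    # One center insert plus four on a 50 mm ring at 90° spacing,
    # in the order XT-CF20 (center), wood (N), air (E), ABS (S), bronze (W).
    r = 50.0
    return [
        Insert(TABLE_MATERIALS["XT-CF20"], (0.0, 0.0)),
        Insert(TABLE_MATERIALS["wood"], (0.0, r)),
        Insert(TABLE_MATERIALS["air"], (r, 0.0)),
        Insert(TABLE_MATERIALS["ABS"], (0.0, -r)),
        Insert(TABLE_MATERIALS["bronze"], (-r, 0.0)),
    ]


@dataclass
class PhantomSpec:
    """Geometry and material table of the digital phantom.

    Defaults give a 512×512 slice at 0.5 mm spacing (25.6 cm field of view)
    around the 16 cm case.  ``background_mu`` is the attenuation of the bulk
    printed case (water-like PLA, 0.190 cm⁻¹ by default); ``air_mu`` fills
    everything outside the case.
    """

    matrix_size: int = 512
    pixel_spacing: float = 0.5  # mm per pixel
    case_outer_diameter: float = 160.0  # mm
    case_shell_thickness: float = 2.0  # mm
    background_mu: float = 0.190  # cm^-1
    air_mu: float = 0.0
    inserts: list[Insert] = field(default_factory=_default_inserts)

    def validate(self) -> None:
        if self.matrix_size < 1:
            raise PhantomGeometryError("matrix_size must be >= 1")
        if self.pixel_spacing <= 0:
            raise PhantomGeometryError("pixel_spacing must be positive")
        if self.matrix_size * self.pixel_spacing < self.case_outer_diameter:
            raise PhantomGeometryError(
                "field of view smaller than the case: "
                f"{self.matrix_size} px × {self.pixel_spacing} mm < {self.case_outer_diameter} mm"
            )
        names = [ins.material.name for ins in self.inserts]
        if len(set(names)) != len(names):
            raise PhantomGeometryError(f"duplicate insert material names: {names}")
        r_int = self.case_outer_diameter / 2 - self.case_shell_thickness
        for ins in self.inserts:
            cx, cy = ins.center
            if math.hypot(cx, cy) + ins.diameter / 2 > r_int:
                raise PhantomGeometryError(
                    f"insert {ins.material.name!r} extends outside the case interior "
                    f"(|center|={math.hypot(cx, cy):.1f} mm + r={ins.diameter / 2:.1f} mm "
                    f"> {r_int:.1f} mm)"
                )
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                gap = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if gap < (a.diameter + b.diameter) / 2:
                    raise PhantomGeometryError(
                        f"inserts {a.material.name!r} and {b.material.name!r} overlap "
                        f"(centers {gap:.1f} mm apart)"
                    )

    def insert_by_tissue(self, tissue: str) -> Insert:
        for ins in self.inserts:
            if ins.material.mimics == tissue:
                return ins
        raise KeyError(f"no insert mimics tissue {tissue!r}")

    # -- pixel-coordinate helpers -------------------------------------------------

    def to_pixel(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        """Map an (x right, y up) offset from the image center to (row, col)."""
        n = self.matrix_size
        col = n / 2 + x_mm / self.pixel_spacing - 0.5
        row = n / 2 - y_mm / self.pixel_spacing - 0.5
        return row, col


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian noise injection parameters.

    ``intensity`` is interpreted as the noise variance on the [0, 1] image
    when ``mode="variance"`` (the MATLAB ``imnoise`` convention) or as the
    standard deviation when ``mode="std"``.
    """

    intensity: float
    seed: int | None = None
    mode: str = "variance"
    clip: bool = True
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"noise intensity must be >= 0, got {self.intensity}")
        if self.mode not in ("variance", "std"):
            raise ValueError(f"mode must be 'variance' or 'std', got {self.mode!r}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.intensity) if self.mode == "variance" else self.intensity


def _pixel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centers, mm, origin at image center."""
    n = spec.matrix_size
    d = spec.pixel_spacing
    coords = (np.arange(n) + 0.5) * d - n * d / 2
    x = coords[None, :]
    y = -coords[:, None]  # row index grows downward
    return x, y


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Rasterize the noiseless phantom slice.

    A pixel belongs to a circle iff its center lies inside it (no
    anti-aliasing), which keeps ROI statistics exactly piecewise constant on
    the clean image.  Values are clipped to [0, 1].
    """
    spec.validate()
    x, y = _pixel_centers(spec)
    values = np.full((spec.matrix_size, spec.matrix_size), spec.air_mu, dtype=float)
    r_case = spec.case_outer_diameter / 2
    case = x**2 + y**2 <= r_case**2
    values[case] = spec.background_mu
    for ins in spec.inserts:
        cx, cy = ins.center
        disk = (x - cx) ** 2 + (y - cy) ** 2 <= (ins.diameter / 2) ** 2
        values[disk] = ins.material.mu
    np.clip(values, 0.0, 1.0, out=values)
    return ImageGrid(values, dx=spec.pixel_spacing, dy=spec.pixel_spacing)


def add_gaussian_noise(img: ImageGrid, noise: NoiseSpec) -> ImageGrid:
    """Add i.i.d. zero-mean Gaussian noise and (by default) clamp to [0, 1].

    Identical ``NoiseSpec.seed`` values give bit-identical output.
    """
    if not isinstance(noise, NoiseSpec):
        raise TypeError("noise must be a NoiseSpec")
    rng = np.random.default_rng(noise.seed)
    out = img.values + rng.normal(noise.mean, noise.sigma, size=img.shape)
    if noise.clip:
        np.clip(out, 0.0, 1.0, out=out)
    result = img.with_values(out)
    result.meta.update(noise_intensity=noise.intensity, noise_mode=noise.mode, seed=noise.seed)
    return result


# -- default ROI layout (metric, background, NNPS and visual regions) -------------


def _centered_roi(spec: PhantomSpec, center_mm: tuple[float, float], size: int, role: str, label: str) -> ROI:
    row, col = spec.to_pixel(*center_mm)
    r0 = int(round(row - (size - 1) / 2))
    c0 = int(round(col - (size - 1) / 2))
    return ROI(row0=r0, col0=c0, height=size, width=size, role=role, label=label)


def default_roi_layout(
    spec: PhantomSpec,
    material_roi_size: int = 15,
    nnps_roi_size: int = 64,
    nnps_inset: int = 4,
) -> ROILayout:
    """Build the standard measurement layout on the phantom.

    One square ROI centered in each tissue-mimicking insert (CSF, GM, WM),
    one background ROI per material ROI in nearby case bulk (offset 45° on
    the insert ring), four NNPS ROIs in the scan-air corners, and one visual
    ROI straddling the central insert's boundary.

    Raises
    ------
    ROILayoutError
        If an ROI does not fit inside its insert or crosses a material
        boundary of the clean phantom.
    """
    spec.validate()
    clean = generate_phantom(spec)
    rois: list[ROI] = []
    pairing: dict[str, str] = {}

    half_diag = material_roi_size * spec.pixel_spacing / math.sqrt(2)
    ring = 50.0  # mm, matches the default insert ring
    bg_angle = {"CSF": 45.0, "GM": 45.0, "WM": 225.0}
    for tissue in ("CSF", "GM", "WM"):
        ins = spec.insert_by_tissue(tissue)
        if half_diag > ins.diameter / 2:
            raise ROILayoutError(
                f"{material_roi_size}×{material_roi_size} ROI does not fit inside the "
                f"{ins.diameter:.0f} mm {tissue} insert at {spec.pixel_spacing} mm spacing"
            )
        rois.append(_centered_roi(spec, ins.center, material_roi_size, "material", tissue))
        # background in case bulk: on the insert ring rotated by 45°, or at
        # half the ring radius for the central insert
        ang = math.radians(bg_angle[tissue])
        radius = ring if math.hypot(*ins.center) > 1e-9 else ring / 2
        bg_center = (radius * math.cos(ang), radius * math.sin(ang))
        rois.append(_centered_roi(spec, bg_center, material_roi_size, "background", f"{tissue}_bg"))
        pairing[tissue] = f"{tissue}_bg"

    n = spec.matrix_size
    a, s = nnps_inset, nnps_roi_size
    for k, (r0, c0) in enumerate([(a, a), (a, n - a - s), (n - a - s, a), (n - a - s, n - a - s)]):
        rois.append(ROI(row0=r0, col0=c0, height=s, width=s, role="nnps", label=f"air_{k}"))

    # visual ROI spanning the CSF insert / background boundary
    center_ins = spec.insert_by_tissue("CSF")
    edge = (center_ins.center[0] + center_ins.diameter / 2, center_ins.center[1])
    rois.append(_centered_roi(spec, edge, material_roi_size, "visual", "edge"))

    layout = ROILayout(rois=rois, pairing=pairing)
    layout.validate(clean.shape)

    # material/background ROIs must not cross a material boundary; NNPS ROIs
    # must sit in scan air
    for roi in layout.rois:
        patch = roi.extract(clean.values)
        if roi.role in ("material", "background") and np.ptp(patch) > 0:
            raise ROILayoutError(f"ROI {roi.label!r} crosses a material boundary")
        if roi.role == "nnps" and not np.allclose(patch, spec.air_mu):
            raise ROILayoutError(f"NNPS ROI {roi.label!r} is not fully in scan air")
    return layout
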