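"""Comparative metric tables and improvement-ratio summaries.

A :class:`MetricTable` holds one metric (CNR or COV) on the full grid
(noise intensity × algorithm × material region).  Improvement ratios compare
a target algorithm with a reference per cell: for CNR (higher is better) the
ratio is target/reference; for COV (lower is better) it is reference/target,
so an improvement is always a factor above 1.

The package bundles reference CNR and COV tables measured on scanner CT
images of the physical 3D-printed brain phantom (five noise intensities ×
five processing conditions × three tissue regions), so the summary
operations are testable without any image computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import ImageGrid
from .metrics import ROILayout, cnr as _cnr, cov as _cov

__all__ = [
    "MetricTable",
    "ImprovementSummary",
    "RatioExtremes",
    "build_metric_table",
    "improvement_ratios",
    "ratio_extremes",
    "load_reference_table",
]

_COLUMNS = ["noise_intensity", "algorithm", "material", "value"]
ALGORITHMS = ("Noisy", "Gaussian", "Wiener", "TV", "FNLM")


def round2(x: float) -> float:
    """Two-decimal rounding, half away from zero (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricTable:
    """One metric over the (noise intensity × algorithm × material) grid."""

    df: pd.DataFrame
    metric: str  # "CNR" | "COV"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"metric table missing columns {missing}")
        self.df = self.df[_COLUMNS].reset_index(drop=True)
        if not np.all(np.isfinite(self.df["value"])):
            raise ValueError("metric table contains non-finite values")
        if self.metric == "COV" and (self.df["value"] <= 0).any():
            raise ValueError("COV values must be positive")
        # completeness over the declared axes
        expected = {
            (v, a, m)
            for v in self.noise_intensities
            for a in self.algorithms
            for m in self.materials
        }
        present = set(map(tuple, self.df[["noise_intensity", "algorithm", "material"]].itertuples(index=False)))
        absent = sorted(expected - present)
        if absent:
            raise ValueError(f"metric table incomplete; missing cells: {absent}")
        if len(present) != len(self.df):
            raise ValueError("metric table contains duplicate cells")

    @property
    def noise_intensities(self) -> list[float]:
        return sorted(self.df["noise_intensity"].unique())

    @property
    def algorithms(self) -> list[str]:
        return list(self.df["algorithm"].unique())

    @property
    def materials(self) -> list[str]:
        return list(self.df["material"].unique())

    def value(self, noise_intensity: float, algorithm: str, material: str) -> float:
        sel = self.df[
            (self.df["noise_intensity"] == noise_intensity)
            & (self.df["algorithm"] == algorithm)
            & (self.df["material"] == material)
        ]
        if len(sel) != 1:
            raise KeyError((noise_intensity, algorithm, material))
        return float(sel["value"].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metric: str) -> "MetricTable":
        return cls(pd.read_csv(path), metric=metric)


def build_metric_table(
    images: Mapping[tuple[float, str], ImageGrid],
    layout: ROILayout,
    metric: str,
) -> MetricTable:
    """Score every (noise intensity, algorithm) image on every material ROI.

    ``images`` maps (noise_intensity, algorithm) to the processed image.
    Missing grid cells raise a completeness error listing the absent keys.
    """
    if metric not in ("CNR", "COV"):
        raise ValueError(f"metric must be 'CNR' or 'COV', got {metric!r}")
    noises = sorted({k[0] for k in images})
    algs = list(dict.fromkeys(k[1] for k in images))
    absent = [(v, a) for v in noises for a in algs if (v, a) not in images]
    if absent:
        raise ValueError(f"missing images for cells: {absent}")
    rows = []
    for (v, alg), img in images.items():
        for mat in layout.material_labels:
            roi = layout[mat]
            if metric == "CNR":
                val = _cnr(img, roi, layout.background_for(mat))
            else:
                val = _cov(img, roi)
            rows.append((v, alg, mat, val))
    return MetricTable(pd.DataFrame(rows, columns=_COLUMNS), metric=metric)


@dataclass(frozen=True)
class RatioExtremes:
    min: float
    max: float
    min_at: tuple[float, str]  # (noise intensity, material)
    max_at: tuple[float, str]


@dataclass
class ImprovementSummary:
    """Per-cell improvement ratios of a target algorithm over a reference."""

    metric: str
    target: str
    reference: str
    ratios: pd.DataFrame  # noise_intensity, material, ratio (unrounded)
    per_noise_mean: pd.Series  # indexed by noise intensity

    @property
    def extremes(self) -> RatioExtremes:
        i_min = self.ratios["ratio"].idxmin()
        i_max = self.ratios["ratio"].idxmax()
        rmin, rmax = self.ratios.loc[i_min], self.ratios.loc[i_max]
        return RatioExtremes(
            min=round2(rmin["ratio"]),
            max=round2(rmax["ratio"]),
            min_at=(float(rmin["noise_intensity"]), str(rmin["material"])),
            max_at=(float(rmax["noise_intensity"]), str(rmax["material"])),
        )

    def rounded_ratios(self) -> pd.DataFrame:
        out = self.ratios.copy()
        out["ratio"] = out["ratio"].map(round2)
        return out


def improvement_ratios(table: MetricTable, target: str = "FNLM", reference: str = "Noisy") -> ImprovementSummary:
    """Per-cell improvement factors of ``target`` relative to ``reference``.

    For CNR the ratio is target/reference; for COV (lower is better) it is
    reference/target.  A zero-valued denominator raises an error naming the
    offending cell.
    """
    for alg in (target, reference):
        if alg not in table.algorithms:
            raise ValueError(f"algorithm {alg!r} not present in table (has {table.algorithms})")
    rows = []
    for v in table.noise_intensities:
        for mat in table.materials:
            t = table.value(v, target, mat)
            r = table.value(v, reference, mat)
            num, den = (t, r) if table.metric == "CNR" else (r, t)
            if den == 0:
                raise ValueError(f"undefined ratio: zero denominator in cell ({v}, {mat})")
            rows.append((v, mat, num / den))
    ratios = pd.DataFrame(rows, columns=["noise_intensity", "material", "ratio"])
    per_noise = ratios.groupby("noise_intensity")["ratio"].mean()
    return ImprovementSummary(
        metric=table.metric, target=target, reference=reference, ratios=ratios, per_noise_mean=per_noise
    )


def ratio_extremes(summary: ImprovementSummary) -> RatioExtremes:
    """Global minimum and maximum per-cell ratios with their table coordinates."""
    if summary.ratios.empty:
        raise ValueError("summary is empty")
    return summary.extremes


def load_reference_table(metric: str) -> MetricTable:
    """Load the bundled scanner-measured reference table for ``metric``."""
    name = {"CNR": "reference_cnr_table.csv", "COV": "reference_cov_table.csv"}[metric]
    with resources.files("ctdenoise.data").joinpath(name).open("rb") as fh:
        return MetricTable(pd.read_csv(fh), metric=metric)
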