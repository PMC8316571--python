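"""Hounsfield-unit material classification and the trapezoidal opacity curve.

The classifier carries a built-in table of CT values for the calcium
compounds found in the human body; otoconia are calcium carbonate
(140-250 HU, 189 +/- 38.4), well separated from skull bone (400-850 HU),
which is what makes threshold-based extraction of the otolith organs
possible in the first place.

The transfer function used for rendering is a trapezoid over 140-850 HU:
an upward ramp from the minimum CaCO3 value (140) to the minimum skull
value (400), a plateau at full opacity from 400 to 600 (the mean skull
value of an elderly skull), and a downward ramp from 600 to 850 (the mean
skull value under 55 years). Voxels outside 140-850 HU are fully
transparent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import CTVolume, Mask

__all__ = [
    "MaterialDefinition",
    "OpacityCurve",
    "builtin_materials",
    "get_material",
    "material_mask",
    "opacity",
]


@dataclass(frozen=True)
class MaterialDefinition:
    """A material identified by a closed HU range, optionally with the
    published mean +/- SD of that range."""

    name: str
    low: float
    high: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError(f"{self.name}: low must be <= high")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.mean is not None and not (self.low <= self.mean <= self.high):
            # kept as published even when internally inconsistent
            warnings.warn(
                f"{self.name}: published mean {self.mean} lies outside the "
                f"published range [{self.low}, {self.high}]"
            )


# Published CT values of calcium compounds (HU). The struvite row is kept
# exactly as published although its mean falls outside its printed range;
# the skull row has a range only.
_MATERIALS = (
    ("CaCO3", 140, 250, 189.0, 38.4),
    ("hydroxyapatite", 2289, 2433, 2361.0, 36.0),
    ("calcium oxalate", 1810, 1914, 1862.0, 26.0),
    ("brushite", 2087, 2223, 2155.0, 34.0),
    ("calcium oxide", 2200, 3100, 2650.0, 83.0),
    ("calcium hydroxide", 1500, 2000, 1803.0, 146.0),
    ("struvite", 987, 1187, 1248.0, 118.0),
    ("skull", 400, 850, None, None),
)


def builtin_materials() -> list[MaterialDefinition]:
    """The built-in material table: seven calcium compounds plus skull bone."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # struvite row, see _MATERIALS
        return [MaterialDefinition(*row) for row in _MATERIALS]


def get_material(name: str) -> MaterialDefinition:
    """Look up a built-in material by (case-insensitive) name."""
    for m in builtin_materials():
        if m.name.lower() == name.lower():
            return m
    raise KeyError(f"unknown material {name!r}")


def material_mask(volume: CTVolume, material: MaterialDefinition) -> Mask:
    """Boolean mask of voxels with ``low <= HU <= high`` (closed range)."""
    data = (volume.voxels >= material.low) & (volume.voxels <= material.high)
    return Mask(data, volume.spacing_mm, volume.origin_mm)


@dataclass(frozen=True)
class OpacityCurve:
    """Trapezoidal opacity transfer function over HU.

    Zero outside ``(ramp_up_start, ramp_down_end)``, ``max_opacity`` on
    ``[plateau_start, plateau_end]``, linear on both ramps.
    """

    ramp_up_start: float = 140.0
    plateau_start: float = 400.0
    plateau_end: float = 600.0
    ramp_down_end: float = 850.0
    max_opacity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ramp_up_start < self.plateau_start <= self.plateau_end < self.ramp_down_end):
            raise ValueError(
                "breakpoints must satisfy ramp_up_start < plateau_start "
                "<= plateau_end < ramp_down_end"
            )
        if not 0.0 <= self.max_opacity <= 1.0:
            raise ValueError("max_opacity must be in [0, 1]")


def opacity(hu, curve: OpacityCurve | None = None):
    """Opacity fraction in [0, max_opacity] for scalar or array HU input.

    Piecewise linear and continuous; exactly zero at and beyond both feet
    of the trapezoid.
    """
    if curve is None:
        curve = OpacityCurve()
    xp = [curve.ramp_up_start, curve.plateau_start, curve.plateau_end, curve.ramp_down_end]
    fp = [0.0, curve.max_opacity, curve.max_opacity, 0.0]
    out = np.interp(hu, xp, fp, left=0.0, right=0.0)
    if np.isscalar(hu):
        return float(out)
    return out
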