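"""Dimension and volume measurement of segmented aggregates.

Width and length of a macula are defined orientation-free: voxel centers
are taken in world mm, the principal axes are the eigenvectors of the
centered second-moment matrix, and each extent is the max-minus-min
projection of the voxel centers onto an axis. Extents are reported sorted
descending as length >= width >= thickness. Volume is voxel count times
voxel volume.

Raw max-minus-min of voxel *centers* underestimates an object's extent by
up to one voxel; the ``compensate`` toggle adds one voxel diagonal to each
extent to quantify that discretization bias, and is off by default so the
measurement definition stays minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import Mask

__all__ = ["MaculaMeasurement", "CohortSummary", "measure_region", "summarize", "summarize_cohort"]


@dataclass
class MaculaMeasurement:
    """Principal-axis dimensions (mm) and volume (mm^3) of one aggregate."""

    label: int
    length_mm: float
    width_mm: float
    thickness_mm: float
    volume_mm3: float
    centroid_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.length_mm >= self.width_mm >= self.thickness_mm >= 0:
            raise ValueError("extents must satisfy length >= width >= thickness >= 0")
        if self.volume_mm3 < 0:
            raise ValueError("volume must be >= 0")


def measure_region(mask: Mask, label: int = 0, compensate: bool = False) -> MaculaMeasurement:
    """Measure one region given as a boolean mask on a CT grid."""
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise ValueError("cannot measure an empty mask")
    spacing = np.asarray(mask.spacing_mm)
    origin = np.asarray(mask.origin_mm)
    pts = origin + idx * spacing  # voxel centers, world mm
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    if compensate:
        extents = extents + math.sqrt(float((spacing**2).sum()))
    length, width, thickness = np.sort(extents)[::-1]
    volume = len(pts) * float(np.prod(spacing))
    return MaculaMeasurement(
        label=label,
        length_mm=float(length),
        width_mm=float(width),
        thickness_mm=float(thickness),
        volume_mm3=volume,
        centroid_mm=tuple(float(c) for c in centroid),
    )


@dataclass(frozen=True)
class _Summary:
    mean: float
    sd: float
    n: int


def summarize(values: Sequence[float]):
    """Mean and sample SD (n-1 denominator) of a sequence of measurements.

    Returns a :class:`otolithct.stats.SummaryStats`; requires n >= 2
    because the sample SD is undefined for a single observation.
    """
    from .stats import SummaryStats

    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to form a summary (sample SD)")
    return SummaryStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=int(vals.size))


@dataclass
class CohortSummary:
    """Per-dimension summaries of a cohort of measurements of one organ."""

    group: str
    length_mm: object
    width_mm: object
    thickness_mm: object
    volume_mm3: object
    n: int


def summarize_cohort(measurements: Sequence[MaculaMeasurement], group: str) -> CohortSummary:
    """Summarize a cohort (one organ, e.g. ``"utricle"`` or ``"saccule"``)
    as mean +/- sample SD per dimension."""
    if len(measurements) < 2:
        raise ValueError("need at least 2 measurements per cohort")
    return CohortSummary(
        group=group,
        length_mm=summarize([m.length_mm for m in measurements]),
        width_mm=summarize([m.width_mm for m in measurements]),
        thickness_mm=summarize([m.thickness_mm for m in measurements]),
        volume_mm3=summarize([m.volume_mm3 for m in measurements]),
        n=len(measurements),
    )
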