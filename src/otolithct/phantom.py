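"""Synthetic temporal-bone CT phantom with known ground truth.

The phantom emulates the only contrast that matters to the method: a
bony-labyrinth shell at skull HU (default mean 625, inside the published
400-850 skull range), water-like intralabyrinthine fluid (default
15 +/- 10 HU; no published value exists for endolymph/perilymph, so this
is a configurable assumption), and one or more macula/otolith aggregates
at CaCO3 HU (default 189 +/- 38.4). Outside the shell is air at -1000 HU.
Cochlea and semicircular-canal geometry, beam hardening and
partial-volume physics beyond optional Gaussian smoothing are not
modeled.

Every compartment draws per-voxel Gaussian HU noise from a seeded
generator, so the same seed reproduces the volume bit for bit. The truth
object records, per aggregate, the analytic extents and volume alongside
the rasterized mask, enabling parameter-recovery tests of the full
segmentation and measurement chain.

Default geometry places an utricle-like blob (2.2 x 2.7 mm in plane) and
a saccule-like blob (1.1 x 2.6 mm) inside the shell lumen, matching the
histological scale of the reference table. Slab thickness is 1.2 mm,
chosen so that a 0.5 mm slice pitch intersects each blob with three
slice planes; thinner slabs are representable but alias badly at the
default slice spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .measure import MaculaMeasurement
from .volume_io import HU_MAX, HU_MIN, CTVolume, Mask

__all__ = [
    "BlobConfig",
    "LabyrinthConfig",
    "PhantomConfig",
    "PhantomTruth",
    "BlobTruth",
    "default_config",
    "silence",
    "generate_phantom",
    "truth_measurements",
]

Triple = tuple[float, float, float]


class BlobConfig(BaseModel):
    """One macula/otolith aggregate.

    ``semi_axes_mm`` are ordered (slice, row, column). A ``peanut`` is the
    union of two ellipsoids with shared semi-axes whose centers sit at
    +/- ``lobe_offset_mm`` along the blob's longest axis.
    """

    label: str
    shape: Literal["ellipsoid", "peanut"] = "ellipsoid"
    center_mm: Triple
    semi_axes_mm: Triple
    lobe_offset_mm: float = Field(default=0.0, ge=0.0)
    hu_mean: float = Field(default=189.0, ge=140.0, le=250.0)
    hu_sd: float = Field(default=38.4, ge=0.0)

    @model_validator(mode="after")
    def _positive_axes(self):
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"{self.label}: semi-axes must be > 0")
        if self.shape == "peanut" and self.lobe_offset_mm <= 0:
            raise ValueError(f"{self.label}: peanut needs lobe_offset_mm > 0")
        return self


class LabyrinthConfig(BaseModel):
    """Ellipsoidal bony-labyrinth shell."""

    center_mm: Triple
    outer_semi_axes_mm: Triple
    wall_thickness_mm: float = Field(default=0.8, gt=0.0)
    wall_hu_mean: float = Field(default=625.0, ge=400.0, le=850.0)
    wall_hu_sd: float = Field(default=50.0, ge=0.0)

    @model_validator(mode="after")
    def _geometry(self):
        if any(a <= 0 for a in self.outer_semi_axes_mm):
            raise ValueError("outer semi-axes must be > 0")
        if any(self.wall_thickness_mm >= a for a in self.outer_semi_axes_mm):
            raise ValueError("wall thickness must be smaller than every semi-axis")
        return self

    @property
    def lumen_semi_axes_mm(self) -> Triple:
        return tuple(a - self.wall_thickness_mm for a in self.outer_semi_axes_mm)


class PhantomConfig(BaseModel):
    """Full phantom description; identical configs and seeds give
    bit-identical volumes."""

    shape: tuple[int, int, int] = (32, 72, 72)
    spacing_mm: Triple = (0.5, 0.18, 0.18)
    origin_mm: Triple = (0.0, 0.0, 0.0)
    labyrinth: LabyrinthConfig
    fluid_hu_mean: float = 15.0
    fluid_hu_sd: float = Field(default=10.0, ge=0.0)
    background_hu: float = -1000.0
    maculae: list[BlobConfig] = Field(default_factory=list)
    noise_sd: float = Field(default=0.0, ge=0.0)
    smoothing_mm: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if any(n < 1 for n in self.shape):
            raise ValueError("shape axes must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be > 0")
        bad = [b.label for b in self.maculae if not _blob_inside_lumen(b, self.labyrinth)]
        if bad:
            raise ValueError(f"blobs outside the labyrinth lumen: {bad}")
        return self


def _unit_sphere_dirs(n: int = 256) -> np.ndarray:
    # Fibonacci sphere; deterministic surface sampling for containment checks.
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([z, r * np.cos(phi), r * np.sin(phi)], axis=1)


def _blob_inside_lumen(blob: BlobConfig, lab: LabyrinthConfig) -> bool:
    lumen = np.asarray(lab.lumen_semi_axes_mm)
    lcenter = np.asarray(lab.center_mm)
    semi = np.asarray(blob.semi_axes_mm)
    centers = [np.asarray(blob.center_mm)]
    if blob.shape == "peanut":
        axis = np.zeros(3)
        axis[int(np.argmax(semi))] = blob.lobe_offset_mm
        centers = [centers[0] - axis, centers[0] + axis]
    dirs = _unit_sphere_dirs()
    for c in centers:
        surface = c + dirs * semi
        q = ((surface - lcenter) / lumen) ** 2
        if np.any(q.sum(axis=1) > 1.0):
            return False
    return True


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> PhantomConfig:
    """Default two-macula phantom at the published acquisition geometry.

    Volume 32 x 72 x 72 voxels at 0.50 x 0.18 x 0.18 mm. The shell is a
    5.5 mm sphere with a 0.8 mm wall centered on a voxel. The utricle-like
    blob has in-plane extents 2.2 x 2.7 mm and the saccule-like blob
    1.1 x 2.6 mm, both 1.2 mm thick, placed on opposite sides of the
    lumen. HU distributions follow the published material table.
    """
    shell_center = (8.0, 6.48, 6.48)
    lab = LabyrinthConfig(center_mm=shell_center, outer_semi_axes_mm=(5.5, 5.5, 5.5))
    utricle = BlobConfig(
        label="utricle",
        center_mm=(8.0, 4.86, 7.92),
        semi_axes_mm=(0.6, 1.1, 1.35),  # extents 1.2 x 2.2 x 2.7 mm
    )
    saccule = BlobConfig(
        label="saccule",
        center_mm=(8.0, 8.10, 5.04),
        semi_axes_mm=(0.6, 0.55, 1.3),  # extents 1.2 x 1.1 x 2.6 mm
    )
    return PhantomConfig(labyrinth=lab, maculae=[utricle, saccule], seed=seed)


def silence(config: PhantomConfig) -> PhantomConfig:
    """Copy of a config with every HU noise source and smoothing set to
    zero: each compartment takes exactly its mean HU."""
    cfg = config.model_copy(deep=True)
    cfg.noise_sd = 0.0
    cfg.smoothing_mm = 0.0
    cfg.fluid_hu_sd = 0.0
    cfg.labyrinth.wall_hu_sd = 0.0
    for blob in cfg.maculae:
        blob.hu_sd = 0.0
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class BlobTruth:
    """Ground truth for one aggregate."""

    label: str
    center_mm: Triple
    extents_mm: Triple  # sorted descending: length, width, thickness
    analytic_volume_mm3: float
    voxel_volume_mm3: float
    mask: Mask


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    blobs: list[BlobTruth]
    shell_mask: Mask
    lumen_mask: Mask


def _analytic_volume(blob: BlobConfig) -> float:
    a, b, c = blob.semi_axes_mm
    v_ell = 4.0 / 3.0 * math.pi * a * b * c
    if blob.shape == "ellipsoid":
        return v_ell
    # Peanut: two ellipsoids offset along the longest axis. Mapping that
    # configuration onto unit spheres (divide each coordinate by its
    # semi-axis) turns the overlap into the lens of two unit spheres at
    # center distance d, whose volume is (pi/12)(4 + d)(2 - d)^2; volumes
    # scale back by abc.
    d = 2.0 * blob.lobe_offset_mm / float(max(blob.semi_axes_mm))
    if d >= 2.0:
        return 2.0 * v_ell
    lens = (math.pi / 12.0) * (4.0 + d) * (2.0 - d) ** 2 * a * b * c
    return 2.0 * v_ell - lens


def _blob_extents(blob: BlobConfig) -> Triple:
    ext = 2.0 * np.asarray(blob.semi_axes_mm)
    if blob.shape == "peanut":
        ext[int(np.argmax(ext))] += 2.0 * blob.lobe_offset_mm
    return tuple(float(e) for e in np.sort(ext)[::-1])


def _ellipsoid_mask(coords, center, semi) -> np.ndarray:
    q = ((coords[0] - center[0]) / semi[0]) ** 2
    q = q[:, None, None] + (((coords[1] - center[1]) / semi[1]) ** 2)[None, :, None]
    q = q + (((coords[2] - center[2]) / semi[2]) ** 2)[None, None, :]
    return q <= 1.0


def _blob_mask(coords, blob: BlobConfig) -> np.ndarray:
    center = np.asarray(blob.center_mm)
    semi = np.asarray(blob.semi_axes_mm)
    if blob.shape == "ellipsoid":
        return _ellipsoid_mask(coords, center, semi)
    axis = np.zeros(3)
    axis[int(np.argmax(semi))] = blob.lobe_offset_mm
    return _ellipsoid_mask(coords, center - axis, semi) | _ellipsoid_mask(coords, center + axis, semi)


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom config into a CT volume plus ground truth.

    Compartment assignment order is background, fluid, wall, then blobs
    (later compartments overwrite earlier ones). Per-voxel HU draws come
    from ``numpy.random.default_rng(config.seed)`` in a fixed order, so
    the volume is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    sz, sy, sx = config.spacing_mm
    oz, oy, ox = config.origin_mm
    coords = (
        oz + np.arange(nz) * sz,
        oy + np.arange(ny) * sy,
        ox + np.arange(nx) * sx,
    )

    lab = config.labyrinth
    outer = _ellipsoid_mask(coords, np.asarray(lab.center_mm), np.asarray(lab.outer_semi_axes_mm))
    lumen = _ellipsoid_mask(coords, np.asarray(lab.center_mm), np.asarray(lab.lumen_semi_axes_mm))
    shell = outer & ~lumen

    hu = np.full(config.shape, float(config.background_hu))

    def fill(mask: np.ndarray, mean: float, sd: float) -> None:
        n = int(mask.sum())
        if n == 0:
            return
        hu[mask] = mean if sd == 0 else rng.normal(mean, sd, size=n)

    fill(lumen, config.fluid_hu_mean, config.fluid_hu_sd)
    fill(shell, lab.wall_hu_mean, lab.wall_hu_sd)

    blobs: list[BlobTruth] = []
    voxel_volume = float(sz * sy * sx)
    for blob in config.maculae:
        bmask = _blob_mask(coords, blob)
        fill(bmask, blob.hu_mean, blob.hu_sd)
        blobs.append(
            BlobTruth(
                label=blob.label,
                center_mm=tuple(blob.center_mm),
                extents_mm=_blob_extents(blob),
                analytic_volume_mm3=_analytic_volume(blob),
                voxel_volume_mm3=float(bmask.sum()) * voxel_volume,
                mask=Mask(bmask, config.spacing_mm, config.origin_mm),
            )
        )

    if config.noise_sd > 0:
        hu = hu + rng.normal(0.0, config.noise_sd, size=hu.shape)
    if config.smoothing_mm > 0:
        sigma = [config.smoothing_mm / s for s in config.spacing_mm]
        hu = ndimage.gaussian_filter(hu, sigma=sigma)
    hu = np.clip(hu, HU_MIN, HU_MAX)

    volume = CTVolume(hu, config.spacing_mm, config.origin_mm)
    truth = PhantomTruth(
        blobs=blobs,
        shell_mask=Mask(shell, config.spacing_mm, config.origin_mm),
        lumen_mask=Mask(lumen, config.spacing_mm, config.origin_mm),
    )
    return volume, truth


def truth_measurements(truth: PhantomTruth) -> list[MaculaMeasurement]:
    """Analytic truth converted to the measurement output type, for
    parameter-recovery comparisons."""
    out = []
    for i, blob in enumerate(truth.blobs, start=1):
        length, width, thickness = blob.extents_mm
        out.append(
            MaculaMeasurement(
                label=i,
                length_mm=length,
                width_mm=width,
                thickness_mm=thickness,
                volume_mm3=blob.analytic_volume_mm3,
                centroid_mm=blob.center_mm,
            )
        )
    return out
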