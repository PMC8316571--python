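"""Binary mathematical morphology for otolith-aggregate segmentation.

The segmentation chain is: threshold the volume to the CaCO3 range,
optionally intersect with a vestibule region of interest, label connected
components, then per component identify a seed voxel, extract the inner
contour, and thicken the contour with a structuring-element pair.

The hit-miss transform (HMT) probes each position with two disjoint offset
sets: B1 must fall entirely on foreground, B2 entirely on background.
Thickening is ``X | HMT(X, (B1, B2))`` -- matched background positions are
promoted to foreground, so the operation can only grow a mask.

Probes that fall outside the grid count as background: a B1 probe off the
edge fails, a B2 probe off the edge succeeds. This keeps the operators
conservative at the phantom boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .classify import MaterialDefinition, material_mask
from .volume_io import CTVolume, Mask

__all__ = [
    "StructuringElementPair",
    "border_growth_pairs",
    "hit_miss",
    "identify_seeds",
    "extract_contour",
    "thicken",
    "Region",
    "segment_aggregates",
]

Offset = tuple[int, int, int]


@dataclass(frozen=True)
class StructuringElementPair:
    """Foreground probe set B1 and background probe set B2, as voxel
    offsets relative to the origin of the element."""

    b1: frozenset
    b2: frozenset

    def __init__(self, b1: Iterable[Sequence[int]], b2: Iterable[Sequence[int]] = ()):
        b1s = frozenset(tuple(int(v) for v in off) for off in b1)
        b2s = frozenset(tuple(int(v) for v in off) for off in b2)
        if b1s & b2s:
            raise ValueError(f"B1 and B2 overlap at {sorted(b1s & b2s)}")
        for off in b1s | b2s:
            if len(off) != 3:
                raise ValueError(f"offsets must be 3D, got {off}")
        object.__setattr__(self, "b1", b1s)
        object.__setattr__(self, "b2", b2s)


def border_growth_pairs() -> list[StructuringElementPair]:
    """The 8 canonical in-plane border-growth pairs, applied slice-wise.

    Each pair matches a background voxel (B2 = origin) whose in-plane
    neighbor in one of the 8 directions is foreground (B1 = that
    neighbor); thickening with all 8 grows a contour by one in-plane
    voxel layer.
    """
    pairs = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            pairs.append(StructuringElementPair(b1=[(0, dr, dc)], b2=[(0, 0, 0)]))
    return pairs


def _shifted(data: np.ndarray, offset: Offset, fill: bool) -> np.ndarray:
    """``out[x] = data[x + offset]``, with out-of-bounds positions = fill."""
    out = np.full_like(data, fill)
    src = []
    dst = []
    for n, d in zip(data.shape, offset):
        lo, hi = max(0, d), min(n, n + d)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - d, hi - d))
    out[tuple(dst)] = data[tuple(src)]
    return out


def _erode_offsets(data: np.ndarray, offsets: frozenset, border: bool) -> np.ndarray:
    # Erosion by an arbitrary offset set; empty set erodes to all-true.
    out = np.ones_like(data)
    for off in offsets:
        out &= _shifted(data, off, border)
    return out


def hit_miss(x: Mask, se: StructuringElementPair) -> Mask:
    """Hit-miss transform: true where every B1 offset lands on foreground
    and every B2 offset lands on background (out-of-bounds = background)."""
    fg = _erode_offsets(x.data, se.b1, border=False)
    bg = _erode_offsets(~x.data, se.b2, border=True)
    return x.like(fg & bg)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def identify_seeds(x: Mask, connectivity: int = 26) -> list[tuple[int, int, int]]:
    """One seed per connected component: its lexicographically smallest
    voxel (scan order slice, row, column)."""
    labels, n = ndimage.label(x.data, structure=_structure(connectivity))
    if n == 0:
        return []
    # C-order flat scan is lexicographic; first occurrence per label.
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    seeds = []
    for v, f in zip(values, first):
        if v == 0:
            continue
        seeds.append(tuple(int(i) for i in np.unravel_index(f, labels.shape)))
    return seeds


def extract_contour(x: Mask, connectivity: int = 6) -> Mask:
    """Inner boundary: X minus its erosion by the connectivity
    neighborhood (voxels outside the grid count as background)."""
    eroded = ndimage.binary_erosion(
        x.data, structure=_structure(connectivity), border_value=0
    )
    return x.like(x.data & ~eroded)


def thicken(x: Mask, se: StructuringElementPair) -> Mask:
    """``X | HMT(X, se)`` -- never removes voxels."""
    return x.like(x.data | hit_miss(x, se).data)


@dataclass
class Region:
    """One segmented CaCO3 aggregate."""

    label: int
    mask: Mask
    seed: tuple[int, int, int]
    contour: Mask
    thickened: Mask

    @property
    def voxel_count(self) -> int:
        return self.mask.count()


def segment_aggregates(
    volume: CTVolume,
    caco3: MaterialDefinition,
    roi: Mask | None = None,
    se_pairs: Sequence[StructuringElementPair] | None = None,
    connectivity: int = 26,
    contour_connectivity: int = 6,
    min_voxels: int = 5,
) -> list[Region]:
    """Segment CaCO3 aggregates in a CT volume.

    Thresholds to the material range, intersects with ``roi`` when given,
    labels connected components (default 26-connectivity so that thin
    slabs at 0.5 mm slice spacing do not fragment), drops components below
    ``min_voxels``, and per region computes the seed, the inner contour
    (6-connectivity erosion) and the contour thickened with ``se_pairs``
    (default: the 8 in-plane border-growth pairs applied in sequence).
    """
    if se_pairs is None:
        se_pairs = border_growth_pairs()
    mask = material_mask(volume, caco3)
    if roi is not None:
        if roi.shape != mask.shape:
            raise ValueError("roi shape does not match volume shape")
        mask = mask.like(mask.data & roi.data)
    if mask.count() == 0:
        warnings.warn("no CaCO3 voxels found; empty segmentation")
        return []

    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    regions: list[Region] = []
    out_label = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        if int(comp.sum()) < min_voxels:
            continue
        out_label += 1
        comp_mask = mask.like(comp)
        seed = identify_seeds(comp_mask, connectivity)[0]
        contour = extract_contour(comp_mask, contour_connectivity)
        thick = contour
        for se in se_pairs:
            thick = thicken(thick, se)
        regions.append(
            Region(label=out_label, mask=comp_mask, seed=seed, contour=contour, thickened=thick)
        )
    if not regions:
        warnings.warn("all CaCO3 components below the minimum size; empty segmentation")
    return regions
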