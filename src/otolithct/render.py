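"""Front-cut grayscale direct volume rendering.

The display pipeline mirrors a workstation skull preset reduced to its
reproducible core: voxels in front of the structure of interest are removed
with a cutting plane (front cut), then the remaining volume is projected
orthographically with front-to-back alpha compositing through the
trapezoidal opacity curve. Shading is opacity-driven monochrome: the gray
value of a pixel is ``brightness x accumulated_opacity``, with no lighting
model, matching black-and-white shading at constant 100% brightness.

Compositing recurrence per ray sample (front to back):
``A <- A + (1 - A) * alpha(HU)``; equivalently ``A = 1 - prod(1 - alpha_i)``.
A sample with alpha = 1 saturates the ray, so everything behind it is
occluded exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import OpacityCurve, opacity
from .volume_io import HU_MIN, CTVolume

__all__ = ["CutPlane", "RenderedImage", "apply_cut", "render_projection"]

_AXIS_VIEWS = {
    "z+": (0, False), "z-": (0, True),
    "y+": (1, False), "y-": (1, True),
    "x+": (2, False), "x-": (2, True),
}
# axis naming: z = slice axis (0), y = row axis (1), x = column axis (2);
# "z+" looks along increasing slice index (rays travel +z).


@dataclass(frozen=True)
class CutPlane:
    """An oriented plane; voxels on the positive side of the normal are
    removed (set fully transparent)."""

    point_mm: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("cut-plane normal must be non-zero")
            object.__setattr__(self, "normal", tuple(n / norm))


@dataclass
class RenderedImage:
    """A 2D grayscale projection, values in [0, 1]."""

    pixels: np.ndarray
    pitch_mm: tuple[float, float]
    view: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("rendered gray values must lie in [0, 1]")


def apply_cut(volume: CTVolume, plane: CutPlane) -> CTVolume:
    """Remove the half-space in front of the plane.

    Voxels whose center has positive signed distance along the plane
    normal are set to -1024 HU (air, fully transparent under any curve
    with a foot above air); the rest are untouched.
    """
    out = volume.copy()
    coords = [
        volume.origin_mm[a] + np.arange(volume.shape[a]) * volume.spacing_mm[a]
        for a in range(3)
    ]
    p = np.asarray(plane.point_mm, dtype=float)
    n = np.asarray(plane.normal, dtype=float)
    signed = (
        (coords[0][:, None, None] - p[0]) * n[0]
        + (coords[1][None, :, None] - p[1]) * n[1]
        + (coords[2][None, None, :] - p[2]) * n[2]
    )
    out.voxels = np.where(signed > 0, HU_MIN, out.voxels)
    return out


def _render_axis(volume, axis, reverse, curve, brightness):
    alpha = opacity(volume.voxels, curve)
    alpha = np.moveaxis(alpha, axis, 0)
    if reverse:
        alpha = alpha[::-1]
    # A = 1 - prod(1 - alpha) along the ray; exact occlusion behind alpha=1.
    transparency = np.prod(1.0 - alpha, axis=0)
    accumulated = 1.0 - transparency
    other = [a for a in range(3) if a != axis]
    pitch = (volume.spacing_mm[other[0]], volume.spacing_mm[other[1]])
    return np.clip(brightness * accumulated, 0.0, 1.0), pitch


def _orthonormal_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, v)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(v, helper)
    u /= np.linalg.norm(u)
    w = np.cross(v, u)
    return u, w


def _render_oblique(volume, view, curve, brightness):
    from scipy.ndimage import map_coordinates

    v = np.asarray(view, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("view vector must be non-zero")
    v = v / norm
    u, w = _orthonormal_basis(v)

    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)
    extent = spacing * (np.asarray(volume.shape) - 1)
    corners = np.array(
        [[origin + extent * np.array(b) for b in np.ndindex(2, 2, 2)]]
    ).reshape(-1, 3)
    center = origin + extent / 2

    pu = (corners - center) @ u
    pw = (corners - center) @ w
    pv = (corners - center) @ v
    pitch = float(spacing.min())
    nu = int(np.ceil((pu.max() - pu.min()) / pitch)) + 1
    nw = int(np.ceil((pw.max() - pw.min()) / pitch)) + 1
    ns = int(np.ceil((pv.max() - pv.min()) / pitch)) + 1

    iu = pu.min() + np.arange(nu) * pitch
    iw = pw.min() + np.arange(nw) * pitch
    accumulated = np.zeros((nw, nu))
    grid_w, grid_u = np.meshgrid(iw, iu, indexing="ij")
    base = center + grid_w[..., None] * w + grid_u[..., None] * u
    for step in range(ns):
        depth = pv.min() + step * pitch
        pts = base + depth * v
        idx = (pts - origin) / spacing  # world -> fractional index
        hu = map_coordinates(
            volume.voxels.astype(float),
            [idx[..., 0], idx[..., 1], idx[..., 2]],
            order=1,
            mode="constant",
            cval=HU_MIN,
        )
        alpha = opacity(hu, curve)
        accumulated = accumulated + (1.0 - accumulated) * alpha
    return np.clip(brightness * accumulated, 0.0, 1.0), (pitch, pitch)


def render_projection(
    volume: CTVolume,
    view: str | tuple[float, float, float] = "z-",
    curve: OpacityCurve | None = None,
    brightness: float = 1.0,
) -> RenderedImage:
    """Orthographic front-to-back compositing projection.

    ``view`` is one of ``z+ z- y+ y- x+ x-`` (one ray sample per voxel
    crossed, nearest-neighbor HU lookup) or an arbitrary direction vector
    (trilinear resampling at the smallest voxel pitch). Gray value is
    ``brightness`` times the accumulated opacity.
    """
    if curve is None:
        curve = OpacityCurve()
    if not 0.0 <= brightness <= 1.0:
        raise ValueError("brightness must be in [0, 1]")
    if isinstance(view, str):
        if view not in _AXIS_VIEWS:
            raise ValueError(f"unknown view {view!r}; expected one of {sorted(_AXIS_VIEWS)}")
        axis, reverse = _AXIS_VIEWS[view]
        pixels, pitch = _render_axis(volume, axis, reverse, curve, brightness)
        return RenderedImage(pixels, pitch, view)
    pixels, pitch = _render_oblique(volume, view, curve, brightness)
    return RenderedImage(pixels, pitch, f"vector{tuple(round(float(c), 4) for c in view)}")


def save_png(image: RenderedImage, path) -> None:
    """Write a 16-bit grayscale PNG."""
    from PIL import Image

    arr = np.round(image.pixels * 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))
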