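"""Warping of the moving view and two-color fused output.

Once the pose of the moving view is known, its image is resampled into
the fixed view's physical frame and the pair is rendered as a two-channel
overlay (fixed in red, moving in green over black), the view a clinician
reads for angulation and displacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .geometry import Polyline, RigidTransform

__all__ = ["GrayImage", "Canvas", "FusedView", "warp_image", "fuse", "transform_polyline"]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel raster with isotropic spacing and mm origin offset."""

    pixels: np.ndarray  # 2D float, row = y, col = x
    spacing: float  # mm per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # mm position of pixel (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("image must be 2D")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def extent_mm(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of pixel centers in mm."""
        h, w = self.pixels.shape
        ox, oy = self.origin
        return (ox, oy, ox + (w - 1) * self.spacing, oy + (h - 1) * self.spacing)


@dataclass(frozen=True)
class Canvas:
    """Output grid: mm origin, isotropic spacing, and (height, width)."""

    origin: tuple[float, float]
    spacing: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("degenerate canvas")


@dataclass(frozen=True)
class FusedView:
    """Fixed and warped-moving channels on a shared canvas."""

    fixed: np.ndarray
    moving: np.ndarray
    canvas: Canvas
    transform: RigidTransform

    def __post_init__(self) -> None:
        if self.fixed.shape != self.moving.shape:
            raise ValueError("fused channels must share shape")

    def to_rgb(self) -> np.ndarray:
        """8-bit RGB render: fixed -> red, moving -> green, blue zero."""

        def norm(ch: np.ndarray) -> np.ndarray:
            lo, hi = float(ch.min()), float(ch.max())
            if hi <= lo:
                return np.zeros_like(ch, dtype=np.uint8)
            return ((ch - lo) / (hi - lo) * 255).astype(np.uint8)

        rgb = np.zeros((*self.fixed.shape, 3), dtype=np.uint8)
        rgb[..., 0] = norm(self.fixed)
        rgb[..., 1] = norm(self.moving)
        return rgb

    def save(self, png_path, meta_path=None) -> None:
        iio.imwrite(png_path, self.to_rgb())
        if meta_path is not None:
            meta = {
                "canvas_origin_mm": list(self.canvas.origin),
                "spacing_mm": self.canvas.spacing,
                "shape": list(self.canvas.shape),
                "transform": self.transform.to_dict(),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)
                fh.write("\n")


def _default_canvas(fixed: GrayImage, moving: GrayImage, t: RigidTransform, margin: float = 5.0) -> Canvas:
    """Union bounding box of the fixed extent and transformed moving extent."""
    fx0, fy0, fx1, fy1 = fixed.extent_mm
    mx0, my0, mx1, my1 = moving.extent_mm
    corners = np.array([[mx0, my0], [mx1, my0], [mx0, my1], [mx1, my1]])
    tc = t.apply_points(corners)
    xmin = min(fx0, tc[:, 0].min()) - margin
    ymin = min(fy0, tc[:, 1].min()) - margin
    xmax = max(fx1, tc[:, 0].max()) + margin
    ymax = max(fy1, tc[:, 1].max()) + margin
    s = fixed.spacing
    shape = (int(np.ceil((ymax - ymin) / s)) + 1, int(np.ceil((xmax - xmin) / s)) + 1)
    return Canvas(origin=(xmin, ymin), spacing=s, shape=shape)


def warp_image(
    img: GrayImage,
    t: RigidTransform,
    canvas: Canvas,
    order: int = 1,
) -> GrayImage:
    """Resample ``img`` under ``t`` onto ``canvas`` (inverse mapping).

    Each output pixel center is mapped through the inverse transform into
    the source image and sampled with bilinear interpolation (``order=1``;
    ``order=0`` for masks).  Pixels falling outside the source are zero.
    """
    inv = t.inverse().to_matrix()
    h, w = canvas.shape
    oy, ox = canvas.origin[1], canvas.origin[0]
    rows, cols = np.mgrid[0:h, 0:w]
    X = ox + cols * canvas.spacing
    Y = oy + rows * canvas.spacing
    sx = inv[0, 0] * X + inv[0, 1] * Y + inv[0, 2]
    sy = inv[1, 0] * X + inv[1, 1] * Y + inv[1, 2]
    # mm -> source pixel indices
    ci = (sx - img.origin[0]) / img.spacing
    ri = (sy - img.origin[1]) / img.spacing
    out = ndimage.map_coordinates(
        img.pixels, [ri, ci], order=order, mode="constant", cval=0.0, prefilter=False
    )
    return GrayImage(out, canvas.spacing, origin=canvas.origin)


def fuse(
    fixed: GrayImage,
    moving: GrayImage,
    t: RigidTransform,
    canvas: Canvas | None = None,
    order: int = 1,
    margin: float = 5.0,
) -> FusedView:
    """Render fixed and transformed moving views onto a shared canvas."""
    if not np.isclose(fixed.spacing, moving.spacing):
        raise ValueError(
            f"spacing mismatch: fixed {fixed.spacing} vs moving {moving.spacing} mm/px; resample first"
        )
    canvas = canvas or _default_canvas(fixed, moving, t, margin=margin)
    fx = warp_image(fixed, RigidTransform(), canvas, order=order)
    mv = warp_image(moving, t, canvas, order=order)
    return FusedView(fixed=fx.pixels, moving=mv.pixels, canvas=canvas, transform=t)


def transform_polyline(poly: Polyline, t: RigidTransform) -> Polyline:
    """Pointwise rigid transform of a polyline (arc length preserved)."""
    return Polyline.from_array(t.apply_points(poly.as_array()), closed=poly.closed)
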