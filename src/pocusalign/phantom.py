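"""Synthetic paired bone-boundary phantoms with full ground truth.

The generator emulates the geometry a longitudinal distal-forearm scan
produces: a long, near-horizontal echogenic diaphysis line, a steeper
metaphyseal flare dropping to the physis, a physis gap, and a short
epiphysis line beyond it.  The opposing view images the opposite cortex,
so the moving boundary is the same curve offset by the bone width; its
raster is mirrored left-right (opposite probe orientation) and displaced
by a seeded random rigid pose.  Fracture angulation tilts the distal
fragment (flare + physis + epiphysis) about the metaphyseal junction and
tilts the growth plate with it.

Everything downstream is measurable against the recorded ground truth:
the continuous polylines, the landmark sets the documented rules imply,
the growth-plate segment, the view-to-view transform (with its flip),
and the angulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .geometry import Point, Polyline, RigidTransform
from .landmarks import BoundaryMask, LandmarkConfig, LandmarkSet, extract_landmarks

__all__ = ["PhantomConfig", "PhantomPair", "generate_pair", "corrupt"]

_VERTEX_STEP = 0.25  # mm between continuous polyline vertices
_MARGIN = 5.0  # mm free border around rendered content
_EPIPHYSIS_LEN = 6.0  # mm of echogenic epiphysis line beyond the physis gap


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomical and imaging parameters of the generated pair (mm).

    Defaults approximate a pediatric distal radius in a ~6 cm scan
    window with ~1 cm bone width.  ``angulation_deg > 0`` tilts the
    distal fragment dorsally about the metaphyseal junction.
    """

    diaphysis_length: float = 60.0
    bone_width: float = 10.0
    physis_gap: float = 3.0
    flare_height: float = 4.0
    flare_length: float = 4.0
    angulation_deg: float = 0.0
    spacing: float = 0.1
    jitter_sd: float = 0.0
    dropout_fraction: float = 0.0
    max_rotation_deg: float = 20.0
    max_translation: float = 20.0
    line_thickness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diaphysis_length", "bone_width", "physis_gap", "flare_height",
                     "flare_length", "spacing", "line_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.dropout_fraction < 0.5:
            raise ValueError("dropout_fraction must lie in [0, 0.5)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class PhantomPair:
    """A generated fixed/moving view pair with complete ground truth."""

    fixed_mask: BoundaryMask
    fixed_poly: Polyline
    fixed_landmarks: LandmarkSet
    growth_plate: tuple[Point, Point]
    moving_mask: BoundaryMask
    moving_poly: Polyline
    moving_landmarks: LandmarkSet
    true_transform: RigidTransform
    true_angulation_deg: float
    config: PhantomConfig
    # epiphysis strokes (beyond the physis gap), rendered into the masks
    # but not part of the main boundary polylines
    fixed_epi: np.ndarray | None = None
    moving_epi: np.ndarray | None = None


def _rot(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _densify(vertices: np.ndarray, step: float = _VERTEX_STEP) -> np.ndarray:
    """Uniform arc-length resampling of a vertex chain."""
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, cum[-1], step)
    s = np.append(s, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(vertices) - 2)
    span = cum[idx + 1] - cum[idx]
    t = (s - cum[idx]) / np.where(span > 0, span, 1.0)
    return vertices[idx] + t[:, None] * (vertices[idx + 1] - vertices[idx])


def _fixed_geometry(cfg: PhantomConfig):
    """Continuous fixed-view geometry in its own (target) frame.

    Returns the main boundary vertices, the epiphysis vertices and the
    growth-plate segment.  The diaphysis lies on y = y0 running rightward
    from the metaphyseal junction; the distal fragment hangs down-left of
    the junction and is rotated by the angulation about the junction.
    """
    junction = np.array([0.0, 0.0])
    # distal fragment in unrotated pose: flare from junction down-left to the physis tip
    physis_tip = junction + np.array([-cfg.flare_length, cfg.flare_height])
    # epiphysis: continuation beyond the physis gap, along the flare direction
    flare_dir = (physis_tip - junction) / np.linalg.norm(physis_tip - junction)
    epi_start = physis_tip + flare_dir * cfg.physis_gap
    epi_end = epi_start + flare_dir * _EPIPHYSIS_LEN
    # angulation: rotate the distal fragment about the junction
    R = _rot(cfg.angulation_deg)
    rot_about = lambda p: junction + R @ (p - junction)
    physis_tip = rot_about(physis_tip)
    epi_start, epi_end = rot_about(epi_start), rot_about(epi_end)
    # growth plate: through the physis tip, perpendicular to the (rotated) shaft axis
    plate_dir = R @ np.array([0.0, 1.0])
    plate = (
        Point(*(physis_tip - plate_dir * 1.0)),
        Point(*(physis_tip + plate_dir * (cfg.bone_width + 1.0))),
    )
    main = _densify(
        np.array([physis_tip, junction, junction + np.array([cfg.diaphysis_length, 0.0])])
    )
    epi = _densify(np.array([epi_start, epi_end]))
    # shift everything onto a positive canvas with a free margin
    shift = _MARGIN - np.vstack([main, epi]).min(axis=0)
    plate = (Point(*(np.array(tuple(plate[0])) + shift)), Point(*(np.array(tuple(plate[1])) + shift)))
    return main + shift, epi + shift, plate


def _rasterize(curves: list[np.ndarray], cfg: PhantomConfig) -> BoundaryMask:
    """Render mm-frame curves into a binary raster at cfg.spacing."""
    allpts = np.vstack(curves)
    if allpts.min() < 0:
        raise ValueError("phantom geometry extends outside the canvas")
    h = int(math.ceil((allpts[:, 1].max() + _MARGIN) / cfg.spacing)) + 1
    w = int(math.ceil((allpts[:, 0].max() + _MARGIN) / cfg.spacing)) + 1
    img = np.zeros((h, w), dtype=bool)
    for pts in curves:
        px = np.round(pts / cfg.spacing).astype(int)
        for (c0, r0), (c1, r1) in zip(px[:-1], px[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            img[rr, cc] = True
    radius = max(1, int(round(cfg.line_thickness / 2.0 / cfg.spacing)))
    img = dilation(img, disk(radius))
    return BoundaryMask(img, cfg.spacing)


def _landmark_cfg() -> LandmarkConfig:
    return LandmarkConfig()


def generate_pair(cfg: PhantomConfig | None = None) -> PhantomPair:
    """Generate a fixed/moving phantom pair with recorded ground truth.

    The moving boundary is the fixed one offset by the bone width (the
    opposite cortex), mirrored about x = 0 and displaced by a seeded
    rigid pose (rotation about the content centroid up to
    ``max_rotation_deg``, translation up to ``max_translation``), then
    shifted onto a fresh positive canvas.  ``true_transform`` (with
    ``pre_flip=True``) maps moving-frame mm coordinates exactly onto the
    fixed frame; at config ``d = w = bone_width`` it zeroes all three
    alignment constraints.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)

    main_f, epi_f, plate = _fixed_geometry(cfg)
    fixed_mask = _rasterize([main_f, epi_f], cfg)
    fixed_poly = Polyline.from_array(main_f)
    fixed_lm = extract_landmarks(fixed_poly, _landmark_cfg())

    # opposite cortex: same curve, offset upward by the bone width so the
    # transformed moving physis sits bone_width above the fixed one
    off = np.array([0.0, -cfg.bone_width])
    main_t, epi_t = main_f + off, epi_f + off

    # seeded rigid displacement about the content centroid, then mirror
    theta = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    u = rng.uniform(-cfg.max_translation, cfg.max_translation, size=2)
    c = main_t.mean(axis=0)
    R = _rot(theta)
    disp = lambda pts: (R @ (pts - c).T).T + c + u
    flip = np.array([-1.0, 1.0])
    main_n, epi_n = disp(main_t) * flip, disp(epi_t) * flip
    # shift onto a positive canvas
    allpts = np.vstack([main_n, epi_n])
    shift = _MARGIN - allpts.min(axis=0)
    main_n, epi_n = main_n + shift, epi_n + shift

    # native = F(R(p_t - c) + c + u) + shift maps target-frame points
    # (fixed curve + cortex offset) into the native moving frame; the true
    # transform is its exact inverse, canonicalized to flip-first form
    m_fwd = np.eye(3)
    m_fwd[:2, :2] = np.diag(flip) @ R
    m_fwd[:2, 2] = np.diag(flip) @ (c + u - R @ c) + shift
    fwd = RigidTransform.from_matrix(m_fwd)
    true_t = fwd.inverse()

    moving_mask = _rasterize([main_n, epi_n], cfg)
    moving_poly = Polyline.from_array(main_n)
    # moving landmarks live on the offset cortex, carried into the native frame
    off_lm = LandmarkSet(
        Point(fixed_lm.L_p.x + off[0], fixed_lm.L_p.y + off[1]),
        Point(fixed_lm.L_d0.x + off[0], fixed_lm.L_d0.y + off[1]),
        Point(fixed_lm.L_d1.x + off[0], fixed_lm.L_d1.y + off[1]),
    )
    moving_lm = off_lm.transformed(fwd)

    pair = PhantomPair(
        fixed_mask=fixed_mask,
        fixed_poly=fixed_poly,
        fixed_landmarks=fixed_lm,
        growth_plate=plate,
        moving_mask=moving_mask,
        moving_poly=moving_poly,
        moving_landmarks=moving_lm,
        true_transform=true_t,
        true_angulation_deg=cfg.angulation_deg,
        config=cfg,
        fixed_epi=epi_f,
        moving_epi=epi_n,
    )
    if cfg.jitter_sd > 0 or cfg.dropout_fraction > 0:
        pair = corrupt(pair, jitter_sd=cfg.jitter_sd,
                       dropout_fraction=cfg.dropout_fraction, seed=cfg.seed)
    return pair


_JITTER_CONTROL_STEP = 3.0  # mm between jitter control points


def _smooth_jitter(n: int, jitter_sd: float, rng) -> np.ndarray:
    """Spatially correlated Gaussian displacement field (n, 2).

    Segmentation error is smooth along the boundary, so the noise is
    drawn at coarse control points and linearly interpolated; the
    per-vertex marginal stays of order jitter_sd.
    """
    n_ctrl = max(2, int(round(n * _VERTEX_STEP / _JITTER_CONTROL_STEP)) + 1)
    ctrl = rng.normal(0.0, jitter_sd, size=(n_ctrl, 2))
    x = np.linspace(0, n_ctrl - 1, n)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(x, np.arange(n_ctrl), ctrl[:, k])
    return out


def _corrupt_curve(pts: np.ndarray, jitter_sd: float, dropout_fraction: float, rng) -> list[np.ndarray]:
    out = pts + _smooth_jitter(len(pts), jitter_sd, rng) if jitter_sd > 0 else pts.copy()
    if dropout_fraction <= 0:
        return [out]
    n = len(out)
    k = int(round(dropout_fraction * n))
    if k == 0:
        return [out]
    start = int(rng.integers(0, n - k))
    pieces = [out[:start], out[start + k :]]
    return [p for p in pieces if len(p) >= 2]


def corrupt(
    pair: PhantomPair,
    jitter_sd: float = 0.3,
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> PhantomPair:
    """Noise-stress a pair: vertex jitter and contiguous dropout.

    Gaussian jitter (sd in mm) perturbs every polyline vertex and a
    contiguous run of ``dropout_fraction`` of the vertices is removed,
    independently per view; the curves are re-rasterized.  All ground
    truth is left untouched, so downstream errors are measured against
    the clean geometry.
    """
    rng = np.random.default_rng(seed)
    cfg = pair.config
    new = {}
    for name, poly, epi in (
        ("fixed", pair.fixed_poly, pair.fixed_epi),
        ("moving", pair.moving_poly, pair.moving_epi),
    ):
        curves = _corrupt_curve(poly.as_array(), jitter_sd, dropout_fraction, rng)
        if not curves:
            raise ValueError("dropout removed the entire boundary")
        render = list(curves)
        if epi is not None:
            render.extend(_corrupt_curve(epi, jitter_sd, 0.0, rng))
        mask = _rasterize(render, cfg)
        new[name] = (mask, Polyline.from_array(max(curves, key=len)))
    return replace(
        pair,
        fixed_mask=new["fixed"][0],
        fixed_poly=new["fixed"][1],
        moving_mask=new["moving"][0],
        moving_poly=new["moving"][1],
    )
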