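"""Fracture angulation against the growth-plate perpendicular.

The clinical protocol measures the dislocation angle of the distal
fragment as the angle between the fragment (or diaphysis) axis and the
line perpendicular to the growth plate.  An intact, non-angulated bone
has its shaft perpendicular to the physis, so the protocol reads 0 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Point
from .landmarks import LandmarkSet

__all__ = ["AngulationInput", "measure_angulation", "axes_from_landmarks"]


@dataclass(frozen=True)
class AngulationInput:
    """Two mm-frame segments: the growth plate and the measured bone axis."""

    growth_plate: tuple[Point, Point]
    distal_axis: tuple[Point, Point]

    def __post_init__(self) -> None:
        for name, (a, b) in (("growth_plate", self.growth_plate), ("distal_axis", self.distal_axis)):
            if a.distance_to(b) == 0.0:
                raise ValueError(f"degenerate {name} segment")


def _direction(seg: tuple[Point, Point]) -> np.ndarray:
    a, b = seg
    v = np.array([b.x - a.x, b.y - a.y])
    return v / np.linalg.norm(v)


def measure_angulation(inp: AngulationInput, signed: bool = False) -> float:
    """Angle in degrees between the distal axis and the plate perpendicular.

    Unsigned (default): the acute angle, in [0, 90]; symmetric in either
    segment's endpoint order and invariant under rigid motion of all
    inputs.  With ``signed=True`` the angle is reported in (-90, 90] with
    the sign of the cross product of plate-perpendicular and axis in the
    y-down frame (positive = axis rotated counter-clockwise on screen
    from the perpendicular).
    """
    g = _direction(inp.growth_plate)
    a = _direction(inp.distal_axis)
    perp = np.array([-g[1], g[0]])
    cosang = float(np.clip(perp @ a, -1.0, 1.0))
    if not signed:
        # fold to the acute angle: segment orientation is irrelevant
        return math.degrees(math.acos(abs(cosang)))
    sinang = float(perp[0] * a[1] - perp[1] * a[0])
    ang = math.degrees(math.atan2(sinang, cosang))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def axes_from_landmarks(lm: LandmarkSet, plate_direction) -> AngulationInput:
    """Build the measurement input from automatic landmarks.

    The measured axis is the diaphysis direction L_d0 -> L_d1; the growth
    plate passes through L_p with the supplied direction (the plate
    orientation is a manual or ground-truth input, not estimated from the
    image).
    """
    v = np.asarray(plate_direction, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("plate direction must be nonzero")
    plate = (lm.L_p, Point(lm.L_p.x + float(v[0]), lm.L_p.y + float(v[1])))
    return AngulationInput(growth_plate=plate, distal_axis=(lm.L_d0, lm.L_d1))
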