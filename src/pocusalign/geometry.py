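"""2D points, polylines and rigid transforms in physical (mm) coordinates.

The package works in the image convention throughout: origin at the top-left
of the raster, x increasing rightward, y increasing downward, and all
physical quantities in millimetres (pixel indices times pixel spacing).
Rotations are counter-clockwise in this x-right/y-down frame, which on
screen appears as a clockwise turn.

A view transform is rigid — rotation ``theta`` plus translation
``(tx, ty)`` — with an optional horizontal pre-flip (mirror about the
``x = 0`` axis) applied before the rigid part.  The pre-flip models the
left-right mirroring between opposing scan orientations of the same bone;
it is a discrete choice and is never part of continuous optimization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point",
    "Polyline",
    "RigidTransform",
    "identity",
]


@dataclass(frozen=True)
class Point:
    """A 2D point in mm, image frame (x right, y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("Point coordinates must be finite")

    def __iter__(self):
        yield self.x
        yield self.y

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Polyline:
    """An ordered open or closed chain of distinct consecutive points."""

    points: tuple[Point, ...]
    closed: bool = False

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValueError("Polyline needs at least 2 points")
        for a, b in zip(pts, pts[1:]):
            if a.x == b.x and a.y == b.y:
                raise ValueError("consecutive polyline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        """Vertices as an (n, 2) float array."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray | Sequence, closed: bool = False) -> "Polyline":
        return cls(tuple(Point(float(x), float(y)) for x, y in np.asarray(arr, dtype=float)), closed)

    @property
    def segment_lengths(self) -> np.ndarray:
        a = self.as_array()
        if self.closed:
            a = np.vstack([a, a[:1]])
        return np.linalg.norm(np.diff(a, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def cumulative_arc(self) -> np.ndarray:
        """Arc-length position of each vertex from the first (open chains)."""
        return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(self.as_array(), axis=0), axis=1))])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion with optional horizontal pre-flip.

    Acts on a point p as ``R(theta) @ F(p) + (tx, ty)`` where ``F`` mirrors
    about x = 0 when ``pre_flip`` is set.  The homogeneous 3x3 view has an
    orthonormal linear part with determinant +1 (-1 with the flip).
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    pre_flip: bool = False

    def __post_init__(self) -> None:
        for v in (self.theta, self.tx, self.ty):
            if not math.isfinite(v):
                raise ValueError("transform parameters must be finite")

    # -- matrix view ------------------------------------------------------

    def to_matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix; flip (if any) acts before rotation."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        f = -1.0 if self.pre_flip else 1.0
        return np.array(
            [
                [c * f, -s, self.tx],
                [s * f, c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Recover (theta, tx, ty, pre_flip) from a homogeneous matrix.

        The linear part must be orthonormal with determinant +/-1.
        """
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 homogeneous matrix")
        lin = m[:2, :2]
        det = float(np.linalg.det(lin))
        if not math.isclose(abs(det), 1.0, abs_tol=1e-6):
            raise ValueError("linear part is not orthonormal (|det| != 1)")
        pre_flip = det < 0
        # undo the flip column-wise to read the rotation angle
        r = lin.copy()
        if pre_flip:
            r[:, 0] = -r[:, 0]
        theta = math.atan2(r[1, 0], r[0, 0])
        return cls(theta=theta, tx=float(m[0, 2]), ty=float(m[1, 2]), pre_flip=pre_flip)

    # -- action -----------------------------------------------------------

    def apply_point(self, p: Point) -> Point:
        x = -p.x if self.pre_flip else p.x
        c, s = math.cos(self.theta), math.sin(self.theta)
        return Point(c * x - s * p.y + self.tx, s * x + c * p.y + self.ty)

    def apply_vector(self, v: Sequence[float]) -> np.ndarray:
        """Linear part only — displacements do not see the translation."""
        vx, vy = float(v[0]), float(v[1])
        if self.pre_flip:
            vx = -vx
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([c * vx - s * vy, s * vx + c * vy])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized apply_point on an (n, 2) array."""
        pts = np.asarray(pts, dtype=float)
        out = (self.to_matrix()[:2, :2] @ pts.T).T
        out[:, 0] += self.tx
        out[:, 1] += self.ty
        return out

    # -- algebra ----------------------------------------------------------

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform acting as self after other: (self . other)(p).

        Two pre-flips collapse to none (the product has determinant +1).
        """
        return RigidTransform.from_matrix(self.to_matrix() @ other.to_matrix())

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.to_matrix()))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta_deg": math.degrees(self.theta),
            "tx_mm": self.tx,
            "ty_mm": self.ty,
            "pre_flip": self.pre_flip,
            "matrix": [[float(v) for v in row] for row in self.to_matrix()],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            theta=math.radians(float(d["theta_deg"])),
            tx=float(d["tx_mm"]),
            ty=float(d["ty_mm"]),
            pre_flip=bool(d["pre_flip"]),
        )

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def identity() -> RigidTransform:
    return RigidTransform()
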