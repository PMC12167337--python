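"""Bone-boundary landmark extraction.

A segmented bone boundary arrives as a binary raster (one echogenic
boundary stroke per view).  The stroke is reduced to a one-pixel-wide
skeleton, ordered into a polyline in physical mm coordinates, and three
anatomical landmarks are derived from it:

``L_p``
    the physis (growth plate) point — the lower-left extremity of the
    boundary, where the echogenic line breaks at the cartilaginous plate;
``L_d1``
    a diaphysis point in the right part of the long near-horizontal shaft
    segment;
``L_d0``
    a second diaphysis point roughly 2-3 cm proximal (leftward along the
    boundary) of ``L_d1``.

The three points are sparse but sufficient to drive the constrained pose
estimation in :mod:`pocusalign.pose`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .geometry import Point, Polyline

__all__ = [
    "BoundaryMask",
    "LandmarkSet",
    "LandmarkConfig",
    "mask_to_polyline",
    "extract_landmarks",
    "landmarks_from_file",
    "landmarks_to_file",
]


class BoundaryError(ValueError):
    """Raised when a mask or polyline cannot support landmark extraction."""


@dataclass(frozen=True)
class BoundaryMask:
    """Binary raster of a segmented bone boundary with isotropic spacing."""

    pixels: np.ndarray  # 2D bool, row = y, col = x
    spacing: float  # mm per pixel

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels).astype(bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("mask must be a 2D raster")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not px.any():
            raise BoundaryError("no boundary: mask has no foreground pixels")


@dataclass(frozen=True)
class LandmarkSet:
    """The three anatomical points in mm: physis and two diaphysis points.

    In the standard (physis-left) orientation ``L_d0.x < L_d1.x``; a
    mirrored boundary yields the mirrored ordering.
    """

    L_p: Point
    L_d0: Point
    L_d1: Point

    def __post_init__(self) -> None:
        if self.L_d0.distance_to(self.L_d1) == 0.0:
            raise ValueError("diaphysis landmarks must be distinct")

    def as_array(self) -> np.ndarray:
        """Rows L_p, L_d0, L_d1 as a (3, 2) array."""
        return np.array([tuple(self.L_p), tuple(self.L_d0), tuple(self.L_d1)])

    def transformed(self, t) -> "LandmarkSet":
        return LandmarkSet(
            t.apply_point(self.L_p), t.apply_point(self.L_d0), t.apply_point(self.L_d1)
        )

    def to_dict(self) -> dict:
        return {
            "L_p": [self.L_p.x, self.L_p.y],
            "L_d0": [self.L_d0.x, self.L_d0.y],
            "L_d1": [self.L_d1.x, self.L_d1.y],
            "units": "mm",
        }


@dataclass(frozen=True)
class LandmarkConfig:
    """Tunables of the landmark rules, all lengths in mm.

    d0_arc_distance
        arc distance from L_d1 back along the boundary to L_d0
        ("approximately 2-3 cm"); default 25.
    min_diaphysis_length
        sliding-window length used to detect the near-horizontal shaft run.
    horizontal_tol_deg
        maximum absolute angle of a window's least-squares direction to the
        x-axis for the window to count as part of the shaft.
    d1_x_percentile
        L_d1 sits at this percentile of x within the longest shaft run;
        below 100 so the metaphyseal flare at the run's end cannot
        contaminate the point.
    physis_x_fraction
        L_p is searched within this leftmost fraction of the boundary's
        x-range.
    physis_lambda
        L_p maximizes (y - lambda*x): "lower" dominates, lambda breaks ties
        toward "left".
    spur_length
        skeleton spurs shorter than this are pruned before the
        two-endpoint topology check.
    physis_side
        'left' for the standard orientation, 'right' for a mirrored
        boundary (the whole rule set is mirrored).
    """

    d0_arc_distance: float = 25.0
    min_diaphysis_length: float = 15.0
    horizontal_tol_deg: float = 25.0
    d1_x_percentile: float = 90.0
    physis_x_fraction: float = 0.35
    physis_lambda: float = 0.2
    spur_length: float = 2.0
    physis_side: str = "left"

    def __post_init__(self) -> None:
        if not 20.0 <= self.d0_arc_distance <= 30.0:
            raise ValueError("d0_arc_distance must lie in [20, 30] mm")
        if self.physis_side not in ("left", "right"):
            raise ValueError("physis_side must be 'left' or 'right'")


# ---------------------------------------------------------------------------
# skeleton -> ordered polyline


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_graph(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    rows, cols = np.nonzero(skel)
    on = set(zip(rows.tolist(), cols.tolist()))
    return {p: [q for d in _NBRS if (q := (p[0] + d[0], p[1] + d[1])) in on] for p in on}


def _prune_spurs(adj: dict, max_len_px: float) -> dict:
    """Iteratively remove endpoint branches shorter than max_len_px."""
    adj = {p: list(n) for p, n in adj.items()}
    changed = True
    while changed:
        changed = False
        endpoints = [p for p, n in adj.items() if len(n) == 1]
        for ep in endpoints:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            # walk from the endpoint to the first branch point
            path = [ep]
            prev, cur = None, ep
            length = 0.0
            while True:
                nxt = [q for q in adj[cur] if q != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                length += math.hypot(cur[0] - prev[0], cur[1] - prev[1])
                if len(adj[cur]) > 2:
                    break
                path.append(cur)
            if len(adj[cur]) > 2 and length < max_len_px:
                for p in path:
                    for q in adj.pop(p, []):
                        if q in adj and p in adj[q]:
                            adj[q].remove(p)
                changed = True
    return adj


def _trace_chain(adj: dict, start: tuple[int, int]) -> list[tuple[int, int]]:
    path = [start]
    prev, cur = None, start
    visited = {start}
    while True:
        nxt = [q for q in adj[cur] if q != prev and q not in visited]
        if not nxt:
            break
        # prefer non-diagonal continuation for stable traversal
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        prev, cur = cur, nxt[0]
        visited.add(cur)
        path.append(cur)
    return path


def mask_to_polyline(mask: BoundaryMask, spur_length: float = 2.0) -> Polyline:
    """Reduce a boundary mask to an ordered polyline in mm.

    The largest connected foreground component is skeletonized to a
    one-pixel-wide curve; spurs below ``2 mm`` are pruned; the remaining
    chain must have exactly two endpoints and is traversed from its
    leftmost endpoint.  Pixel centers are scaled by the mask spacing.
    """
    lbl = cc_label(mask.pixels, connectivity=2)
    if lbl.max() == 0:
        raise BoundaryError("no boundary: mask has no foreground pixels")
    sizes = np.bincount(lbl.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    skel = skeletonize(lbl == keep)
    adj = _pixel_graph(skel)
    if len(adj) < 2:
        raise BoundaryError("no boundary: skeleton degenerate")
    adj = _prune_spurs(adj, max_len_px=spur_length / mask.spacing)
    endpoints = [p for p, n in adj.items() if len(n) == 1]
    if len(endpoints) != 2:
        raise BoundaryError(
            f"ambiguous boundary topology: {len(endpoints)} skeleton endpoints after pruning"
        )
    start = min(endpoints, key=lambda p: (p[1], p[0]))  # leftmost (then topmost)
    chain = _trace_chain(adj, start)
    s = mask.spacing
    return Polyline.from_array([(c * s, r * s) for r, c in chain])


# ---------------------------------------------------------------------------
# polyline -> landmarks


def _window_angle_deg(pts: np.ndarray) -> float:
    """Absolute angle (deg) of the window's principal direction to the x-axis."""
    d = pts - pts.mean(axis=0)
    cov = d.T @ d
    # principal eigenvector of the 2x2 covariance
    w, v = np.linalg.eigh(cov)
    direction = v[:, int(np.argmax(w))]
    ang = math.degrees(math.atan2(direction[1], direction[0]))
    ang = abs(ang)
    return min(ang, 180.0 - ang)


def _point_at_arc(arr: np.ndarray, cum: np.ndarray, s: float) -> Point:
    """Point at arc-length position s, linear interpolation between vertices."""
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(arr) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    p = arr[i] + t * (arr[i + 1] - arr[i])
    return Point(float(p[0]), float(p[1]))


def extract_landmarks(poly: Polyline, cfg: LandmarkConfig | None = None) -> LandmarkSet:
    """Derive {L_p, L_d0, L_d1} from an ordered boundary polyline.

    The long near-horizontal diaphysis run is found with a sliding
    arc-length window; L_d1 sits at the configured x-percentile of that
    run, L_d0 at ``cfg.d0_arc_distance`` back along the boundary toward
    the physis, and L_p maximizes the lower-left score within the
    physis-side fraction of the x-range.
    """
    cfg = cfg or LandmarkConfig()
    if cfg.physis_side == "right":
        mirrored = Polyline.from_array(poly.as_array() * np.array([-1.0, 1.0]))
        lm = extract_landmarks(
            mirrored,
            LandmarkConfig(
                **{**cfg.__dict__, "physis_side": "left"},
            ),
        )
        neg = lambda p: Point(-p.x, p.y)
        return LandmarkSet(neg(lm.L_p), neg(lm.L_d0), neg(lm.L_d1))

    arr = poly.as_array()
    cum = poly.cumulative_arc
    total = float(cum[-1])
    if total < cfg.d0_arc_distance:
        raise BoundaryError("insufficient boundary extent")

    # -- diaphysis run detection -----------------------------------------
    n = len(arr)
    admissible = np.zeros(n, dtype=bool)  # vertex covered by a horizontal window
    j = 0
    any_window = False
    for i in range(n):
        if cum[i] + cfg.min_diaphysis_length > total + 1e-9:
            break
        while j < n - 1 and cum[j] - cum[i] < cfg.min_diaphysis_length:
            j += 1
        if cum[j] - cum[i] < cfg.min_diaphysis_length - 1e-9:
            break
        if _window_angle_deg(arr[i : j + 1]) <= cfg.horizontal_tol_deg:
            admissible[i : j + 1] = True
            any_window = True
    if not any_window:
        raise BoundaryError("diaphysis not found: no near-horizontal run of sufficient length")

    # maximal admissible runs; keep the longest by arc length
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if admissible[i]:
            k = i
            while k + 1 < n and admissible[k + 1]:
                k += 1
            runs.append((i, k))
            i = k + 1
        else:
            i += 1
    i0, i1 = max(runs, key=lambda r: cum[r[1]] - cum[r[0]])
    run = arr[i0 : i1 + 1]

    # -- L_d1: percentile placement inside the run -----------------------
    x_target = float(np.percentile(run[:, 0], cfg.d1_x_percentile))
    rel = int(np.argmin(np.abs(run[:, 0] - x_target)))  # first occurrence on ties
    idx_d1 = i0 + rel
    L_d1 = Point(float(arr[idx_d1, 0]), float(arr[idx_d1, 1]))

    # -- L_d0: arc distance from L_d1 back toward the physis side --------
    # traversal may run either way along the bone; walk in the index
    # direction that decreases x (the physis side in this frame)
    leftward = 1.0 if arr[i1, 0] < arr[i0, 0] else -1.0
    s_d0 = cum[idx_d1] + leftward * cfg.d0_arc_distance
    if s_d0 < -1e-9 or s_d0 > total + 1e-9:
        raise BoundaryError("insufficient boundary extent proximal to L_d1")
    L_d0 = _point_at_arc(arr, cum, s_d0)

    # -- L_p: lower-left extremity ---------------------------------------
    xmin, xmax = float(arr[:, 0].min()), float(arr[:, 0].max())
    cut = xmin + cfg.physis_x_fraction * (xmax - xmin)
    region = arr[arr[:, 0] <= cut]
    if len(region) == 0:
        region = arr
    score = region[:, 1] - cfg.physis_lambda * region[:, 0]
    best = int(np.argmax(score))
    L_p = Point(float(region[best, 0]), float(region[best, 1]))

    return LandmarkSet(L_p=L_p, L_d0=L_d0, L_d1=L_d1)


# ---------------------------------------------------------------------------
# file I/O


def landmarks_to_file(lm: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(lm.to_dict(), fh, indent=2)
        fh.write("\n")


def landmarks_from_file(path) -> LandmarkSet:
    """Load a landmark JSON {"L_p":[x,y],"L_d0":[x,y],"L_d1":[x,y],"units":"mm"}."""
    with open(path) as fh:
        d = json.load(fh)
    missing = [k for k in ("L_p", "L_d0", "L_d1") if k not in d]
    if missing:
        raise ValueError(f"landmark file missing keys: {', '.join(missing)}")
    pts = {}
    for k in ("L_p", "L_d0", "L_d1"):
        v = d[k]
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise ValueError(f"landmark {k} must be a [x, y] pair, got {v!r}")
        pts[k] = Point(float(v[0]), float(v[1]))
    if d.get("units", "mm") != "mm":
        raise ValueError(f"unsupported landmark units {d.get('units')!r}; expected 'mm'")
    return LandmarkSet(**pts)
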