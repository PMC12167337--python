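"""Contour-distance metrics for alignment evaluation.

Directed Hausdorff and (symmetrized) Chamfer distances between point
sets sampled from boundary contours, both in mm.  Several Chamfer
variants circulate; here the symmetric mean of linear nearest-neighbor
distances is the default so both metrics live on the same mm scale.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff as _scipy_dh

from .geometry import Polyline

__all__ = ["directed_hausdorff", "chamfer", "polyline_to_pointset"]


def _as_points(A) -> np.ndarray:
    a = np.asarray(A, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or len(a) == 0:
        raise ValueError("point set must be a non-empty (n, 2) array")
    return a


def directed_hausdorff(A, B) -> float:
    """max over a in A of the distance from a to its nearest point of B."""
    a, b = _as_points(A), _as_points(B)
    return float(_scipy_dh(a, b)[0])


def chamfer(A, B, variant: str = "mean") -> float:
    """Symmetric Chamfer distance between two point sets.

    variant="mean" (default): 0.5*(mean_a min_b |a-b| + mean_b min_a |a-b|),
    the symmetric mean of linear closest distances (same mm scale as the
    Hausdorff distance).  variant="sum" uses sums instead of means;
    variant="squared_mean" averages squared distances.
    """
    a, b = _as_points(A), _as_points(B)
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    if variant == "mean":
        return float(0.5 * (d_ab.mean() + d_ba.mean()))
    if variant == "sum":
        return float(d_ab.sum() + d_ba.sum())
    if variant == "squared_mean":
        return float(0.5 * ((d_ab**2).mean() + (d_ba**2).mean()))
    raise ValueError(f"unknown chamfer variant {variant!r}")


def polyline_to_pointset(poly: Polyline, step: float = 0.5) -> np.ndarray:
    """Arc-length resampling of a polyline at the given mm step.

    Sample positions are 0, step, 2*step, ... along the arc, with the far
    endpoint always included (once).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    arr = poly.as_array()
    if poly.closed:
        arr = np.vstack([arr, arr[:1]])
    seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    s = np.arange(0.0, total, step)
    if total - (s[-1] if len(s) else 0.0) > 1e-12 or len(s) == 0:
        s = np.append(s, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(arr) - 2)
    span = cum[idx + 1] - cum[idx]
    t = np.where(span > 0, (s - cum[idx]) / np.where(span > 0, span, 1.0), 0.0)
    return arr[idx] + t[:, None] * (arr[idx + 1] - arr[idx])
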