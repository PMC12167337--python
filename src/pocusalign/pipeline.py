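"""End-to-end orchestration: masks in, aligned fused view out.

The full chain mirrors how the views are acquired and read: extract an
ordered boundary and landmarks from each view's mask in its native frame
(the moving view has its physis on the opposite side), mirror the moving
landmarks, estimate the rigid pose, and fuse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .fusion import FusedView, GrayImage, fuse
from .geometry import RigidTransform
from .landmarks import (
    BoundaryMask,
    LandmarkConfig,
    LandmarkSet,
    extract_landmarks,
    mask_to_polyline,
)
from .pose import AlignmentConfig, OptimizationTrace, optimize_alignment

__all__ = ["AlignmentResult", "align_masks", "align_landmarks"]


@dataclass(frozen=True)
class AlignmentResult:
    transform: RigidTransform
    fixed_landmarks: LandmarkSet
    moving_landmarks: LandmarkSet  # native frame, pre-flip
    trace: OptimizationTrace
    fused: FusedView | None

    @property
    def final_energy(self) -> float:
        return self.trace.E[-1]


def align_landmarks(
    Lf: LandmarkSet,
    Lm: LandmarkSet,
    cfg: AlignmentConfig | None = None,
    pre_flip: bool = True,
) -> tuple[RigidTransform, OptimizationTrace]:
    """Pose estimation from landmark sets (moving in its native frame)."""
    return optimize_alignment(Lf, Lm, cfg, pre_flip=pre_flip)


def align_masks(
    fixed: BoundaryMask,
    moving: BoundaryMask,
    align_cfg: AlignmentConfig | None = None,
    landmark_cfg: LandmarkConfig | None = None,
    moving_physis_side: str = "right",
    render: bool = True,
) -> AlignmentResult:
    """Full pipeline on a pair of boundary masks.

    The moving view is scanned from the opposite orientation, so its
    physis sits on the mirrored side (``moving_physis_side``, default
    'right') and the estimated transform carries the horizontal pre-flip.
    """
    lcfg = landmark_cfg or LandmarkConfig()
    Lf = extract_landmarks(mask_to_polyline(fixed), lcfg)
    mcfg = replace(lcfg, physis_side=moving_physis_side)
    Lm = extract_landmarks(mask_to_polyline(moving), mcfg)
    t, trace = optimize_alignment(Lf, Lm, align_cfg, pre_flip=True)
    fused = None
    if render:
        fused = fuse(
            GrayImage(fixed.pixels.astype(float), fixed.spacing),
            GrayImage(moving.pixels.astype(float), moving.spacing),
            t,
            order=0,
        )
    return AlignmentResult(
        transform=t, fixed_landmarks=Lf, moving_landmarks=Lm, trace=trace, fused=fused
    )
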