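"""Constrained rigid pose estimation between two landmark sets.

The relative pose of the two views is found by minimizing a weighted sum
of three anatomically motivated penalties over the rigid parameters
(theta, tx, ty); the horizontal pre-flip of the moving view is fixed
beforehand (a discrete choice cannot be descended upon).

Latitudinal constraint C_a
    the two physis points must share their x-component while their
    y-components differ by a prescribed offset d (the bone lies between
    the two imaged cortices):

        C_a = w_x |L^f_{p,x} - T(L^m_p)_x| + w_y |d - L^f_{p,y} + T(L^m_p)_y|

Longitudinal orientation constraint C_o
    the diaphysis direction vectors of the two views must be parallel:

        C_o = || i^f_d - i^m_d ||,   i_d = (L_d0 - L_d1) / ||L_d0 - L_d1||

    with the moving direction taken through the linear part of T and
    normalized by the untransformed segment length.

Longitudinal position constraint C_p
    without it the first two constraints admit a degenerate minimum with
    both diaphyses collinear; the distance from the transformed moving
    diaphysis midpoint to the fixed diaphysis line must instead equal the
    bone width w:

        C_p = | |(T(L^m_{d,mid}) - L^f_{d0}) . n^f| - w |

    where n^f is the unit normal of the fixed diaphysis direction.  With
    w = 0 this reduces to the plain point-to-line distance.

Total energy:  E = w_a C_a + w_o C_o + w_p C_p, minimized by fixed-step
gradient descent with central-difference gradients (the absolute values
make E piecewise smooth; the symmetric difference evaluates to zero at a
symmetric kink, so an exact optimum is a fixed point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Point, RigidTransform
from .landmarks import LandmarkSet

__all__ = [
    "AlignmentConfig",
    "EnergyBreakdown",
    "OptimizationTrace",
    "latitudinal_constraint",
    "orientation_constraint",
    "position_constraint",
    "total_energy",
    "optimize_alignment",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Weights, geometric targets and optimizer settings.

    w_x, w_y weight the two terms inside C_a; w_a, w_o, w_p weight the
    three constraints in the total energy.  d is the target vertical
    physis offset in mm and w the target bone width in mm; when w is None
    it defaults to d (the physis offset doubles as the width estimate).
    The descent runs ``iterations`` fixed steps of size ``learning_rate``.
    ``init`` selects the starting point: "aligned" (default) is the
    closed-form landmark prealignment — rotate the diaphysis directions
    parallel and put the physis on its offset target — which starts the
    descent inside the correct basin; "physis" translates the moving
    physis onto the fixed one at zero rotation; "identity" starts from
    the identity; a (theta_rad, tx, ty) triple gives it explicitly.
    """

    w_x: float = 1.0
    w_y: float = 1.0
    w_a: float = 1.0
    w_o: float = 1.0
    w_p: float = 1.0
    d: float = 10.0
    w: float | None = None
    learning_rate: float = 5e-2
    iterations: int = 10_000
    init: str | tuple[float, float, float] = "aligned"
    fd_step: float = 1e-4
    trace_stride: int = 50

    def __post_init__(self) -> None:
        for name in ("w_x", "w_y", "w_a", "w_o", "w_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.w is not None and self.w <= 0:
            raise ValueError("w must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    @property
    def width(self) -> float:
        return self.d if self.w is None else self.w


@dataclass(frozen=True)
class EnergyBreakdown:
    """The three constraint values and their weighted total."""

    C_a: float
    C_o: float
    C_p: float
    E: float


@dataclass
class OptimizationTrace:
    """Strided per-iteration records of the descent."""

    iterations: list[int] = field(default_factory=list)
    E: list[float] = field(default_factory=list)
    C_a: list[float] = field(default_factory=list)
    C_o: list[float] = field(default_factory=list)
    C_p: list[float] = field(default_factory=list)
    theta: list[float] = field(default_factory=list)
    tx: list[float] = field(default_factory=list)
    ty: list[float] = field(default_factory=list)

    def append(self, it, e, ca, co, cp, th, tx, ty) -> None:
        self.iterations.append(it)
        self.E.append(e)
        self.C_a.append(ca)
        self.C_o.append(co)
        self.C_p.append(cp)
        self.theta.append(th)
        self.tx.append(tx)
        self.ty.append(ty)

    def __len__(self) -> int:
        return len(self.iterations)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iter,E,C_a,C_o,C_p,theta_deg,tx_mm,ty_mm\n")
            for i in range(len(self.iterations)):
                fh.write(
                    f"{self.iterations[i]},{self.E[i]:.6g},{self.C_a[i]:.6g},"
                    f"{self.C_o[i]:.6g},{self.C_p[i]:.6g},"
                    f"{math.degrees(self.theta[i]):.6g},{self.tx[i]:.6g},{self.ty[i]:.6g}\n"
                )


# ---------------------------------------------------------------------------
# constraints


def latitudinal_constraint(
    Lf: LandmarkSet, Lm: LandmarkSet, t: RigidTransform, cfg: AlignmentConfig
) -> float:
    """Physis alignment penalty C_a (x match, y offset by cfg.d)."""
    tp = t.apply_point(Lm.L_p)
    return cfg.w_x * abs(Lf.L_p.x - tp.x) + cfg.w_y * abs(cfg.d - Lf.L_p.y + tp.y)


def orientation_constraint(Lf: LandmarkSet, Lm: LandmarkSet, t: RigidTransform) -> float:
    """Diaphysis parallelism penalty C_o in [0, 2] for rigid transforms."""
    df = np.array([Lf.L_d0.x - Lf.L_d1.x, Lf.L_d0.y - Lf.L_d1.y])
    dm = np.array([Lm.L_d0.x - Lm.L_d1.x, Lm.L_d0.y - Lm.L_d1.y])
    nf, nm = np.linalg.norm(df), np.linalg.norm(dm)
    if nf == 0 or nm == 0:
        raise ValueError("zero-length diaphysis segment")
    i_f = df / nf
    i_m = t.apply_vector(dm) / nm  # untransformed norm, as defined
    return float(np.linalg.norm(i_f - i_m))


def position_constraint(
    Lf: LandmarkSet, Lm: LandmarkSet, t: RigidTransform, cfg: AlignmentConfig
) -> float:
    """Bone-width penalty C_p: |distance(mid^m, fixed diaphysis line) - w|."""
    df = np.array([Lf.L_d0.x - Lf.L_d1.x, Lf.L_d0.y - Lf.L_d1.y])
    nf = np.linalg.norm(df)
    if nf == 0:
        raise ValueError("zero-length fixed diaphysis segment")
    i_f = df / nf
    n_f = np.array([-i_f[1], i_f[0]])  # 90 deg CCW in the y-down frame
    mid = Point((Lm.L_d0.x + Lm.L_d1.x) / 2.0, (Lm.L_d0.y + Lm.L_d1.y) / 2.0)
    tm = t.apply_point(mid)
    dist = abs((tm.x - Lf.L_d0.x) * n_f[0] + (tm.y - Lf.L_d0.y) * n_f[1])
    return abs(dist - cfg.width)


def total_energy(
    Lf: LandmarkSet, Lm: LandmarkSet, t: RigidTransform, cfg: AlignmentConfig
) -> EnergyBreakdown:
    """Weighted sum E = w_a C_a + w_o C_o + w_p C_p."""
    ca = latitudinal_constraint(Lf, Lm, t, cfg)
    co = orientation_constraint(Lf, Lm, t)
    cp = position_constraint(Lf, Lm, t, cfg)
    return EnergyBreakdown(ca, co, cp, cfg.w_a * ca + cfg.w_o * co + cfg.w_p * cp)


# ---------------------------------------------------------------------------
# optimizer


def _make_energy(Lf: LandmarkSet, Lm_f: LandmarkSet, cfg: AlignmentConfig):
    """Closure evaluating (E, C_a, C_o, C_p) from raw floats — the descent's
    hot path, kept free of object construction."""
    fpx, fpy = Lf.L_p.x, Lf.L_p.y
    mpx, mpy = Lm_f.L_p.x, Lm_f.L_p.y
    fdx, fdy = Lf.L_d0.x - Lf.L_d1.x, Lf.L_d0.y - Lf.L_d1.y
    mdx, mdy = Lm_f.L_d0.x - Lm_f.L_d1.x, Lm_f.L_d0.y - Lm_f.L_d1.y
    nfv = math.hypot(fdx, fdy)
    nmv = math.hypot(mdx, mdy)
    if nfv == 0 or nmv == 0:
        raise ValueError("zero-length diaphysis segment")
    ifx, ify = fdx / nfv, fdy / nfv
    nx, ny = -ify, ifx
    fd0x, fd0y = Lf.L_d0.x, Lf.L_d0.y
    midx = (Lm_f.L_d0.x + Lm_f.L_d1.x) / 2.0
    midy = (Lm_f.L_d0.y + Lm_f.L_d1.y) / 2.0
    w_x, w_y, w_a, w_o, w_p = cfg.w_x, cfg.w_y, cfg.w_a, cfg.w_o, cfg.w_p
    d, width = cfg.d, cfg.width
    cos, sin = math.cos, math.sin

    def energy(th: float, tx: float, ty: float):
        c, s = cos(th), sin(th)
        px = c * mpx - s * mpy + tx
        py = s * mpx + c * mpy + ty
        ca = w_x * abs(fpx - px) + w_y * abs(d - fpy + py)
        imx = (c * mdx - s * mdy) / nmv
        imy = (s * mdx + c * mdy) / nmv
        co = math.hypot(ifx - imx, ify - imy)
        qx = c * midx - s * midy + tx
        qy = s * midx + c * midy + ty
        cp = abs(abs((qx - fd0x) * nx + (qy - fd0y) * ny) - width)
        return w_a * ca + w_o * co + w_p * cp, ca, co, cp

    return energy


def _initial_params(Lf: LandmarkSet, Lm_f: LandmarkSet, cfg: AlignmentConfig):
    if cfg.init == "aligned":
        # closed-form prealignment: rotate the moving diaphysis parallel to
        # the fixed one (C_o = 0) and translate the physis onto its offset
        # target (C_a = 0); the descent then only resolves the residual
        th_f = math.atan2(Lf.L_d0.y - Lf.L_d1.y, Lf.L_d0.x - Lf.L_d1.x)
        th_m = math.atan2(Lm_f.L_d0.y - Lm_f.L_d1.y, Lm_f.L_d0.x - Lm_f.L_d1.x)
        th = th_f - th_m
        c, s = math.cos(th), math.sin(th)
        rx = c * Lm_f.L_p.x - s * Lm_f.L_p.y
        ry = s * Lm_f.L_p.x + c * Lm_f.L_p.y
        return th, Lf.L_p.x - rx, (Lf.L_p.y - cfg.d) - ry
    if cfg.init == "physis":
        return 0.0, Lf.L_p.x - Lm_f.L_p.x, Lf.L_p.y - Lm_f.L_p.y
    if cfg.init == "identity":
        return 0.0, 0.0, 0.0
    th, tx, ty = cfg.init
    return float(th), float(tx), float(ty)


def optimize_alignment(
    Lf: LandmarkSet,
    Lm: LandmarkSet,
    cfg: AlignmentConfig | None = None,
    pre_flip: bool = False,
) -> tuple[RigidTransform, OptimizationTrace]:
    """Minimize the total energy over (theta, tx, ty) by gradient descent.

    If ``pre_flip`` is set, the moving landmarks are mirrored about x = 0
    first and the returned transform carries the flip.  The descent is a
    fixed-step subgradient method: central-difference gradients are taken
    in a frame centered on the moving landmarks, with theta scaled by the
    RMS landmark radius so that all three parameter gradients have
    comparable magnitude near the optimum; the returned parameters are
    the best-energy iterate converted back exactly to the image-origin
    parameterization.  Deterministic for fixed inputs.
    """
    cfg = cfg or AlignmentConfig()
    if pre_flip:
        Lm_f = LandmarkSet(
            Point(-Lm.L_p.x, Lm.L_p.y),
            Point(-Lm.L_d0.x, Lm.L_d0.y),
            Point(-Lm.L_d1.x, Lm.L_d1.y),
        )
    else:
        Lm_f = Lm

    # center on the moving landmarks; scale theta by the RMS radius so the
    # rotation lever arm does not dwarf the translation gradients
    pts = Lm_f.as_array()
    cx, cy = pts.mean(axis=0)
    scale = max(float(np.sqrt(((pts - [cx, cy]) ** 2).sum(axis=1).mean())), 1.0)

    Lm_c = LandmarkSet(
        Point(Lm_f.L_p.x - cx, Lm_f.L_p.y - cy),
        Point(Lm_f.L_d0.x - cx, Lm_f.L_d0.y - cy),
        Point(Lm_f.L_d1.x - cx, Lm_f.L_d1.y - cy),
    )
    energy = _make_energy(Lf, Lm_c, cfg)

    th0, tx0, ty0 = _initial_params(Lf, Lm_f, cfg)
    # translation in the centered frame: T_c(p - c) = T(p)  =>  t_c = R c + t
    c0, s0 = math.cos(th0), math.sin(th0)
    tx_c = c0 * cx - s0 * cy + tx0
    ty_c = s0 * cx + c0 * cy + ty0

    lr = cfg.learning_rate
    h = cfg.fd_step
    stride = max(1, cfg.trace_stride)
    trace = OptimizationTrace()

    th, tx, ty = th0, tx_c, ty_c
    e, ca, co, cp = energy(th, tx, ty)
    if not math.isfinite(e):
        raise ArithmeticError("non-finite energy at initialization")
    best = (e, th, tx, ty)
    trace.append(0, e, ca, co, cp, th, tx - (math.cos(th) * cx - math.sin(th) * cy), ty - (math.sin(th) * cx + math.cos(th) * cy))

    h_th = h / scale  # finite-difference step for the scaled theta variable
    for it in range(1, cfg.iterations + 1):
        g_th = (energy(th + h_th, tx, ty)[0] - energy(th - h_th, tx, ty)[0]) / (2 * h)
        g_tx = (energy(th, tx + h, ty)[0] - energy(th, tx - h, ty)[0]) / (2 * h)
        g_ty = (energy(th, tx, ty + h)[0] - energy(th, tx, ty - h)[0]) / (2 * h)
        th -= lr * g_th / scale
        tx -= lr * g_tx
        ty -= lr * g_ty
        e, ca, co, cp = energy(th, tx, ty)
        if not math.isfinite(e):
            err = ArithmeticError(f"non-finite energy at iteration {it}")
            err.trace = trace  # type: ignore[attr-defined]
            raise err
        if e < best[0]:
            best = (e, th, tx, ty)
        if it % stride == 0 or it == cfg.iterations:
            c, s = math.cos(th), math.sin(th)
            trace.append(it, e, ca, co, cp, th, tx - (c * cx - s * cy), ty - (s * cx + c * cy))

    e_b, th_b, tx_b, ty_b = best
    th_b = (th_b + math.pi) % (2 * math.pi) - math.pi  # report in (-pi, pi]
    c, s = math.cos(th_b), math.sin(th_b)
    # convert the centered translation back to the image origin
    result = RigidTransform(
        theta=th_b,
        tx=tx_b - (c * cx - s * cy),
        ty=ty_b - (s * cx + c * cy),
        pre_flip=pre_flip,
    )
    eb, cab, cob, cpb = energy(th_b, tx_b, ty_b)
    trace.append(cfg.iterations, eb, cab, cob, cpb, th_b, result.tx, result.ty)
    return result, trace
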