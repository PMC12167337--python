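import math

import numpy as np
import pytest

from pocusalign import (
    AlignmentConfig,
    LandmarkSet,
    Point,
    RigidTransform,
    latitudinal_constraint,
    optimize_alignment,
    orientation_constraint,
    position_constraint,
    total_energy,
)
from pocusalign.phantom import PhantomConfig, generate_pair
from conftest import phantom_align_config


def lm(p, d0, d1):
    return LandmarkSet(Point(*p), Point(*d0), Point(*d1))


IDENT = RigidTransform()


# ---------------------------------------------------------------------------
# independent brute-force oracles (homogeneous-matrix route, no shared code)


def _matrix(theta, tx, ty, flip):
    F = np.diag([-1.0, 1.0, 1.0]) if flip else np.eye(3)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, tx], [s, c, ty], [0, 0, 1]])
    return R @ F


def _apply(M, p):
    return (M @ [p[0], p[1], 1.0])[:2]


def oracle_ca(Lf, Lm, M, w_x, w_y, d):
    tp = _apply(M, Lm[0])
    return w_x * np.abs(Lf[0][0] - tp[0]) + w_y * np.abs(d - Lf[0][1] + tp[1])


def oracle_co(Lf, Lm, M):
    df = np.subtract(Lf[1], Lf[2])
    dm = np.subtract(Lm[1], Lm[2])
    i_f = df / np.sqrt(df @ df)
    i_m = (M[:2, :2] @ dm) / np.sqrt(dm @ dm)
    return np.sqrt(np.sum((i_f - i_m) ** 2))


def oracle_cp(Lf, Lm, M, w):
    df = np.subtract(Lf[1], Lf[2])
    i_f = df / np.sqrt(df @ df)
    n = np.array([-i_f[1], i_f[0]])
    mid = _apply(M, np.add(Lm[1], Lm[2]) / 2.0)
    return np.abs(np.abs((mid - Lf[1]) @ n) - w)


def random_instance(rng):
    pts = rng.uniform(-50, 50, (6, 2))
    while np.allclose(pts[1], pts[2]) or np.allclose(pts[4], pts[5]):
        pts = rng.uniform(-50, 50, (6, 2))
    Lf, Lm = pts[:3], pts[3:]
    t = RigidTransform(
        rng.uniform(-np.pi, np.pi),
        rng.uniform(-30, 30),
        rng.uniform(-30, 30),
        bool(rng.integers(2)),
    )
    cfg = AlignmentConfig(
        w_x=rng.uniform(0, 2),
        w_y=rng.uniform(0, 2),
        w_a=rng.uniform(0, 2),
        w_o=rng.uniform(0, 2),
        w_p=rng.uniform(0, 2),
        d=rng.uniform(0, 15),
        w=rng.uniform(1, 15),
    )
    return Lf, Lm, t, cfg


class TestLatitudinal:
    def test_exact_satisfaction_is_zero(self):
        cfg = AlignmentConfig(d=4.0, w=4.0)
        Lf = lm((10, 20), (0, 0), (10, 0))
        Lm = lm((10, 16), (0, 5), (10, 5))  # physis exactly d above the fixed one
        assert latitudinal_constraint(Lf, Lm, IDENT, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_manhattan_example(self):
        cfg = AlignmentConfig(w_x=1, w_y=1, d=0)
        Lf = lm((0, 0), (0, 1), (1, 1))
        Lm = lm((3, 4), (0, 1), (1, 1))
        assert latitudinal_constraint(Lf, Lm, IDENT, cfg) == pytest.approx(7.0)

    def test_weight_linearity(self):
        Lf = lm((0, 0), (0, 1), (1, 1))
        Lm = lm((3, 4), (0, 1), (1, 1))
        base = latitudinal_constraint(Lf, Lm, IDENT, AlignmentConfig(w_x=1, w_y=0, d=0))
        double = latitudinal_constraint(Lf, Lm, IDENT, AlignmentConfig(w_x=2, w_y=0, d=0))
        assert double == pytest.approx(2 * base)


class TestOrientation:
    @pytest.mark.parametrize(
        "moving_dir,expected",
        [((1, 0), 0.0), ((-1, 0), 2.0), ((0, 1), math.sqrt(2))],
        ids=["parallel", "antiparallel", "perpendicular"],
    )
    def test_unit_vector_geometry(self, moving_dir, expected):
        Lf = lm((0, 5), (10, 0), (0, 0))  # fixed direction (1, 0)
        Lm = lm(
            (0, 5),
            (10 * moving_dir[0], 10 * moving_dir[1]),
            (0, 0),
        )
        assert orientation_constraint(Lf, Lm, IDENT) == pytest.approx(expected, abs=1e-12)

    def test_zero_length_rejected(self):
        Lf = lm((0, 0), (0, 1), (1, 1))
        with pytest.raises(ValueError):
            LandmarkSet(Point(0, 0), Point(1, 1), Point(1, 1))
        # moving diaphysis collapses only after transform arithmetic; the
        # constructor already guards it, so only the fixed-set path remains
        assert orientation_constraint(Lf, Lf, IDENT) == 0.0


class TestPosition:
    def test_exact_width_is_zero(self):
        cfg = AlignmentConfig(d=7.0, w=7.0)
        Lf = lm((0, 5), (0, 0), (10, 0))
        Lm = lm((0, 12), (0, 7), (10, 7))  # midline exactly 7 mm from fixed line
        assert position_constraint(Lf, Lm, IDENT, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_projection_example(self):
        # fixed diaphysis along x, moving midpoint at (5, 9), width target 7 -> |9-7| = 2
        cfg = AlignmentConfig(d=7.0, w=7.0)
        Lf = lm((0, 5), (0, 0), (10, 0))
        Lm = lm((0, 12), (4, 9), (6, 9))
        assert position_constraint(Lf, Lm, IDENT, cfg) == pytest.approx(2.0)

    def test_zero_width_reduces_to_point_line_distance(self):
        cfg = AlignmentConfig(d=0.0)  # width defaults to d = 0
        Lf = lm((0, 5), (0, 0), (10, 0))
        Lm = lm((0, 12), (4, 9), (6, 9))
        assert position_constraint(Lf, Lm, IDENT, cfg) == pytest.approx(9.0)


class TestTotalEnergy:
    def test_zero_when_all_satisfied(self, phantom_pair):
        pair = phantom_pair
        eb = total_energy(
            pair.fixed_landmarks,
            pair.moving_landmarks,
            pair.true_transform,
            phantom_align_config(pair),
        )
        assert eb.E <= 1e-6

    def test_weighted_sum_identity(self, rng):
        for _ in range(50):
            Lf_a, Lm_a, t, cfg = random_instance(rng)
            Lf = lm(*Lf_a)
            Lm = lm(*Lm_a)
            eb = total_energy(Lf, Lm, t, cfg)
            assert eb.E == pytest.approx(
                cfg.w_a * eb.C_a + cfg.w_o * eb.C_o + cfg.w_p * eb.C_p, abs=1e-12
            )
            assert eb.C_a >= 0 and eb.C_o >= 0 and eb.C_p >= 0
            assert eb.C_o <= 2.0 + 1e-12

    def test_dropping_orientation_weight(self, rng):
        Lf_a, Lm_a, t, cfg = random_instance(rng)
        import dataclasses

        cfg0 = dataclasses.replace(cfg, w_o=0.0)
        eb = total_energy(lm(*Lf_a), lm(*Lm_a), t, cfg0)
        assert eb.E == pytest.approx(cfg.w_a * eb.C_a + cfg.w_p * eb.C_p, abs=1e-12)


class TestOracleEquivalence:
    def test_constraints_match_brute_force(self, rng):
        for _ in range(1000):
            Lf_a, Lm_a, t, cfg = random_instance(rng)
            Lf, Lm = lm(*Lf_a), lm(*Lm_a)
            M = _matrix(t.theta, t.tx, t.ty, t.pre_flip)
            assert latitudinal_constraint(Lf, Lm, t, cfg) == pytest.approx(
                oracle_ca(Lf_a, Lm_a, M, cfg.w_x, cfg.w_y, cfg.d), abs=1e-9
            )
            assert orientation_constraint(Lf, Lm, t) == pytest.approx(
                oracle_co(Lf_a, Lm_a, M), abs=1e-9
            )
            assert position_constraint(Lf, Lm, t, cfg) == pytest.approx(
                oracle_cp(Lf_a, Lm_a, M, cfg.width), abs=1e-9
            )


class TestOptimizer:
    def test_satisfiable_displaced_copy_from_identity_init(self):
        # moving = fixed shifted to the exactly-satisfiable pose nearby
        cfg = AlignmentConfig(d=8.0, w=8.0, init="identity")
        Lf = lm((5, 20), (15, 12), (45, 12))
        Lm = lm((5, 12), (15, 4), (45, 4))  # already exactly at target offset d
        t, trace = optimize_alignment(Lf, Lm, cfg)
        assert trace.E[-1] < 1e-3

    def test_ground_truth_recovery(self, phantom_pair):
        pair = phantom_pair
        t, _ = optimize_alignment(
            pair.fixed_landmarks,
            pair.moving_landmarks,
            phantom_align_config(pair),
            pre_flip=True,
        )
        true = pair.true_transform
        dtheta = math.degrees(
            abs((t.theta - true.theta + math.pi) % (2 * math.pi) - math.pi)
        )
        assert dtheta < 1.0
        assert math.hypot(t.tx - true.tx, t.ty - true.ty) < 1.0

    def test_stationary_at_exact_optimum(self, phantom_pair):
        pair = phantom_pair
        true = pair.true_transform
        cfg = AlignmentConfig(
            d=pair.config.bone_width,
            w=pair.config.bone_width,
            init=(true.theta, true.tx, true.ty),
            iterations=100,
        )
        t, _ = optimize_alignment(
            pair.fixed_landmarks, pair.moving_landmarks, cfg, pre_flip=True
        )
        assert abs(t.theta - true.theta) < 1e-6
        assert math.hypot(t.tx - true.tx, t.ty - true.ty) < 1e-6

    def test_final_energy_not_above_initial(self):
        for seed in range(5):
            pair = generate_pair(PhantomConfig(seed=seed))
            for init in ("aligned", "physis", "identity"):
                cfg = AlignmentConfig(
                    d=pair.config.bone_width,
                    w=pair.config.bone_width,
                    init=init,
                    iterations=2000,
                )
                _, trace = optimize_alignment(
                    pair.fixed_landmarks, pair.moving_landmarks, cfg, pre_flip=True
                )
                assert trace.E[-1] <= trace.E[0] + 1e-12

    def test_translation_equivariance(self, phantom_pair):
        """Translating both views by the same vector leaves the recovered
        rotation unchanged and shifts the translation consistently."""
        pair = phantom_pair
        cfg = phantom_align_config(pair)
        v = np.array([7.0, -3.0])
        t0, _ = optimize_alignment(
            pair.fixed_landmarks, pair.moving_landmarks, cfg, pre_flip=True
        )
        shift = RigidTransform(tx=v[0], ty=v[1])
        Lf_s = pair.fixed_landmarks.transformed(shift)
        Lm_s = pair.moving_landmarks.transformed(shift)
        t1, _ = optimize_alignment(Lf_s, Lm_s, cfg, pre_flip=True)
        assert abs(t1.theta - t0.theta) < 1e-3
        # expected: T1 = shift . T0 . shift^{-1}
        expected = shift.compose(t0).compose(shift.inverse())
        assert math.hypot(t1.tx - expected.tx, t1.ty - expected.ty) < 0.05

    def test_trace_final_matches_returned_transform(self, phantom_pair):
        pair = phantom_pair
        t, trace = optimize_alignment(
            pair.fixed_landmarks, pair.moving_landmarks, phantom_align_config(pair), pre_flip=True
        )
        assert trace.theta[-1] == pytest.approx(t.theta, abs=1e-15)
        assert trace.tx[-1] == pytest.approx(t.tx, abs=1e-12)
        assert trace.ty[-1] == pytest.approx(t.ty, abs=1e-12)

    def test_trace_csv(self, tmp_path, phantom_pair):
        pair = phantom_pair
        _, trace = optimize_alignment(
            pair.fixed_landmarks, pair.moving_landmarks, phantom_align_config(pair), pre_flip=True
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "iter,E,C_a,C_o,C_p,theta_deg,tx_mm,ty_mm"


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_x": -1},
            {"d": -1},
            {"w": 0},
            {"iterations": 0},
            {"learning_rate": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlignmentConfig(**kwargs)

    def test_width_defaults_to_d(self):
        assert AlignmentConfig(d=12.5).width == 12.5
        assert AlignmentConfig(d=12.5, w=9.0).width == 9.0
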