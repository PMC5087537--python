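"""Attitude filter: prediction, adaptive updates, user-frame projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footmotion.attitude import (AttitudeFilter, AttitudeState, DynamicMode,
                                 FilterConfig, acc_residual, dynamic_index,
                                 measurement_matrix, project_stream,
                                 select_mode, tilt_only, to_user_frame)
from footmotion.imu_core import Frame, ImuSample, ImuStream

G = 9.80665


def make_state(rot=None, P=None, t=0.0):
    return AttitudeState(rot=rot or Rotation.identity(),
                         err_state=np.zeros(6),
                         P=np.eye(6) * 1e-4 if P is None else P, t=t)


def static_sample(t, rot=None, gyro=(0, 0, 0)):
    """Sensor-frame sample of a resting IMU with body->nav attitude rot."""
    rot = rot or Rotation.identity()
    return ImuSample(t=t, gyro=gyro, accel=rot.inv().apply([0, 0, G]),
                     frame=Frame.SENSOR)


class TestDynamicIndex:
    def test_rest_is_zero(self):
        assert dynamic_index([0, 0, G], G) == pytest.approx(0.0)

    def test_three_g_sits_on_thres2_boundary(self):
        assert dynamic_index([0, 0, 3 * G], G) == pytest.approx(2 * G)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for a in rng.normal(0, 10, (1000, 3)):
            assert dynamic_index(a, G) == pytest.approx(
                abs(np.sqrt(np.sum(a**2)) - G))


class TestSelectMode:
    def test_zero_index_is_stationary_with_r0(self):
        cfg = FilterConfig()
        mode, R = select_mode(0.0, cfg)
        assert mode is DynamicMode.STATIONARY
        np.testing.assert_allclose(R, cfg.R0)

    def test_two_g_skips_update(self):
        mode, R = select_mode(2 * G, FilterConfig())
        assert mode is DynamicMode.HIGH_DYNAMIC
        assert R is None

    def test_sweep_matches_piecewise_reference(self):
        cfg = FilterConfig()
        rng = np.random.default_rng(1)
        for idx in rng.uniform(0, 3 * G, 10_000):
            mode, R = select_mode(idx, cfg)
            # literal three-branch reference
            if idx < cfg.thres1_eff:
                ref_mode, ref_R = DynamicMode.STATIONARY, cfg.R0
            elif idx < cfg.thres2_eff:
                ref_mode = DynamicMode.LOW_ACCELERATION
                ref_R = cfg.R0 + cfg.k_scale * idx**2 * np.eye(3)
            else:
                ref_mode, ref_R = DynamicMode.HIGH_DYNAMIC, None
            assert mode is ref_mode
            if ref_R is None:
                assert R is None
            else:
                np.testing.assert_allclose(R, ref_R)


class TestPredict:
    def test_zero_gyro_keeps_attitude_and_grows_p_by_q(self):
        flt = AttitudeFilter()
        st = make_state(P=np.zeros((6, 6)))
        out = flt.predict(st, static_sample(0.0), dt=0.01)
        np.testing.assert_allclose(out.C_b_n, np.eye(3), atol=1e-12)
        Q = np.zeros((6, 6))
        Q[:3, :3] = flt.cfg.q_gyro * 0.01 * np.eye(3)
        Q[3:, 3:] = flt.cfg.q_bias * 0.01 * np.eye(3)
        np.testing.assert_allclose(out.P, Q, atol=1e-18)

    def test_constant_rate_about_z_yields_quarter_turn(self):
        flt = AttitudeFilter()
        st = make_state()
        s = ImuSample(t=0, gyro=(0, 0, np.pi / 2), accel=(0, 0, G),
                      frame=Frame.SENSOR)
        for _ in range(1000):
            st = flt.predict(st, s, dt=1e-3)
        yaw, pitch, roll = st.rot.as_euler("ZXY")
        assert yaw == pytest.approx(np.pi / 2, abs=1e-6)
        assert pitch == pytest.approx(0.0, abs=1e-9)
        assert roll == pytest.approx(0.0, abs=1e-9)

    def test_bad_dt_rejected(self):
        flt = AttitudeFilter()
        with pytest.raises(ValueError):
            flt.predict(make_state(), static_sample(0.0), dt=0.0)


class TestResidualAndJacobian:
    def test_perfect_attitude_zero_residual(self):
        rot = Rotation.from_euler("ZXY", [0, 0.3, -0.2])
        st = make_state(rot=rot)
        res = acc_residual(rot.inv().apply([0, 0, G]), st, G)
        np.testing.assert_allclose(res, 0, atol=1e-12)

    def test_one_degree_roll_error_magnitude(self):
        truth = Rotation.identity()
        est = Rotation.from_euler("ZXY", [0, 0, np.deg2rad(1.0)])
        st = make_state(rot=est)
        res = acc_residual(truth.inv().apply([0, 0, G]), st, G)
        assert np.linalg.norm(res) == pytest.approx(G * np.sin(np.deg2rad(1)),
                                                    rel=1e-4)

    def test_residual_matches_first_order_model(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            truth = Rotation.from_rotvec(rng.normal(0, 0.4, 3))
            psi = rng.normal(0, 1, 3)
            psi *= np.deg2rad(rng.uniform(0.1, 1.0)) / np.linalg.norm(psi)
            est = Rotation.from_rotvec(-psi) * truth  # estimate off by psi
            st = make_state(rot=est)
            res = acc_residual(truth.inv().apply([0, 0, G]), st, G)
            lin = measurement_matrix(st, G)[:, :3] @ psi
            assert np.linalg.norm(res - lin) < 0.02 * np.linalg.norm(lin) + 1e-12

    def test_h_structure_at_identity(self):
        H = measurement_matrix(make_state(), G)
        expected = np.zeros((3, 6))
        expected[0, 1] = -G
        expected[1, 0] = G
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_bias_columns_always_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            st = make_state(rot=Rotation.random(rng=rng))
            np.testing.assert_allclose(measurement_matrix(st, G)[:, 3:], 0)

    def test_h_equals_numerical_jacobian(self):
        rng = np.random.default_rng(6)
        eps = 1e-7
        for _ in range(20):
            rot = Rotation.random(rng=rng)
            st = make_state(rot=rot)
            accel = rot.inv().apply([0, 0, G])
            H = measurement_matrix(st, G)[:, :3]
            J = np.zeros((3, 3))
            for j in range(3):
                dpsi = np.zeros(3)
                dpsi[j] = eps
                # applying error -dpsi to the truth moves the estimate by +dpsi
                st_p = make_state(rot=Rotation.from_rotvec(dpsi) * rot)
                res_p = acc_residual(accel, st_p, G)
                # residual(psi) ~ H @ psi with psi the error the update removes
                J[:, j] = -res_p / eps
            np.testing.assert_allclose(H, J, atol=1e-4)


class TestUpdate:
    def test_zero_residual_keeps_attitude_shrinks_p(self):
        flt = AttitudeFilter()
        st = make_state(P=np.eye(6) * 1e-3)
        H = measurement_matrix(st, G)
        out = flt.update(st, np.zeros(3), H, flt.cfg.R0)
        np.testing.assert_allclose(out.C_b_n, st.C_b_n, atol=1e-12)
        assert np.trace(out.P) < np.trace(st.P)

    def test_static_convergence_from_ten_degree_roll_error(self):
        flt = AttitudeFilter()
        truth = Rotation.identity()
        st = make_state(rot=Rotation.from_euler("ZXY", [0, 0, np.deg2rad(10)]),
                        P=np.diag([np.deg2rad(10)**2] * 3 + [0.05**2] * 3))
        rng = np.random.default_rng(7)
        for i in range(1000):  # 5 s at 200 Hz
            accel = truth.inv().apply([0, 0, G]) + rng.normal(0, 0.05, 3)
            s = ImuSample(t=i / 200, gyro=rng.normal(0, 0.005, 3), accel=accel,
                          frame=Frame.SENSOR)
            st, _ = flt.step(st, s, 1 / 200)
        roll_err = abs(st.rot.as_euler("ZXY")[2])
        assert np.rad2deg(roll_err) < 0.5

    def test_p_stays_symmetric_psd_under_random_updates(self):
        flt = AttitudeFilter()
        rng = np.random.default_rng(8)
        st = make_state(P=np.diag(rng.uniform(1e-6, 1e-2, 6)))
        for _ in range(2000):
            st = flt.predict(st, static_sample(st.t, gyro=rng.normal(0, 0.3, 3)),
                             dt=1 / 200)
            H = measurement_matrix(st, G)
            st = flt.update(st, rng.normal(0, 0.1, 3), H, flt.cfg.R0)
            assert np.allclose(st.P, st.P.T, atol=1e-12)
            assert np.linalg.eigvalsh(st.P).min() > -1e-12

    def test_orthonormality_after_feedback(self):
        flt = AttitudeFilter()
        rng = np.random.default_rng(9)
        st = make_state(P=np.eye(6) * 1e-2)
        for _ in range(200):
            st = flt.predict(st, static_sample(st.t, gyro=rng.normal(0, 1, 3)),
                             dt=1 / 200)
            st = flt.update(st, rng.normal(0, 0.5, 3),
                            measurement_matrix(st, G), flt.cfg.R0)
            C = st.C_b_n
            assert np.linalg.norm(C @ C.T - np.eye(3)) < 1e-9
            assert np.linalg.det(C) == pytest.approx(1.0, abs=1e-9)


class TestFilterRuns:
    def test_updates_disabled_equals_pure_gyro_integration(self):
        # accel norm pinned at 3g -> dynamic index 2g -> prediction only
        rng = np.random.default_rng(10)
        n = 400
        gyro = rng.normal(0, 0.5, (n, 3))
        accel = np.tile([0.0, 0.0, 3 * G], (n, 1))
        stream = ImuStream(t=np.arange(n) / 200, gyro=gyro, accel=accel)
        cfg = FilterConfig(init_bias_std=1e-12)
        track = AttitudeFilter(cfg).run(stream)
        assert all(m is DynamicMode.HIGH_DYNAMIC for m in track.mode[1:])
        rot = Rotation.identity()  # leveling on static-looking data gives I
        for i in range(1, n):
            rot = rot * Rotation.from_rotvec(gyro[i] / 200)
        err = (rot.inv() * Rotation.from_quat(track.quat[-1])).magnitude()
        assert err < 1e-8


class TestUserFrame:
    def test_zero_tilt_is_identity(self):
        s = ImuSample(t=0, gyro=(0.1, 0.2, 0.3), accel=(1, 2, 9), frame=Frame.SENSOR)
        out = to_user_frame(s, make_state())
        np.testing.assert_allclose(out.gyro, s.gyro)
        np.testing.assert_allclose(out.accel, s.accel)
        assert out.frame is Frame.USER

    def test_thirty_degree_pitch_recovers_gravity(self):
        rot = Rotation.from_euler("ZXY", [0, np.deg2rad(30), 0])
        s = ImuSample(t=0, gyro=(0, 0, 0), accel=rot.inv().apply([0, 0, G]),
                      frame=Frame.SENSOR)
        out = to_user_frame(s, make_state(rot=rot))
        np.testing.assert_allclose(out.accel, [0, 0, G], atol=1e-10)

    def test_norm_preserved(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rot = Rotation.random(rng=rng)
            s = ImuSample(t=0, gyro=rng.normal(0, 1, 3),
                          accel=rng.normal(0, 5, 3), frame=Frame.SENSOR)
            out = to_user_frame(s, make_state(rot=rot))
            assert np.linalg.norm(out.accel) == pytest.approx(
                np.linalg.norm(s.accel), abs=1e-9)

    def test_yaw_is_stripped(self):
        # a pure-yaw attitude must not change the sample
        rot = Rotation.from_euler("ZXY", [1.2, 0, 0])
        s = ImuSample(t=0, gyro=(0.5, 0, 0), accel=(0, 1, G), frame=Frame.SENSOR)
        out = to_user_frame(s, make_state(rot=rot))
        np.testing.assert_allclose(out.gyro, s.gyro, atol=1e-12)
        np.testing.assert_allclose(out.accel, s.accel, atol=1e-12)

    def test_project_stream_matches_per_sample(self):
        rng = np.random.default_rng(12)
        n = 300
        stream = ImuStream(t=np.arange(n) / 200,
                           gyro=rng.normal(0, 0.2, (n, 3)),
                           accel=np.tile([0.0, 0.0, G], (n, 1))
                           + rng.normal(0, 0.05, (n, 3)))
        flt = AttitudeFilter()
        track = flt.run(stream)
        user = project_stream(stream, track)
        for i in [0, 100, n - 1]:
            st = make_state(rot=track.rotation(i))
            per = to_user_frame(stream[i], st)
            np.testing.assert_allclose(user.accel[i], per.accel, atol=1e-10)
            np.testing.assert_allclose(user.gyro[i], per.gyro, atol=1e-10)
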