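"""Drift-free pitch/roll estimation and user-frame projection.

A shoe-mounted IMU is tilted by an unknown, wearer-dependent pitch/roll
offset.  Gyro integration alone drifts; accelerometer leveling alone is
corrupted by motion.  This module fuses the two with an error-state
Kalman filter whose 6-dimensional state is the small attitude error
``psi`` (rad) plus the gyro bias ``eps_b`` (rad/s, first-order
Gauss-Markov).  The measurement is the body-frame acceleration residual
(measured specific force minus gravity projected through the current
attitude), and its covariance R is tuned adaptively from a dynamic index
``| ||f|| - g |``:

* stationary  (index < thres1):          R = R0
* low acceleration (thres1 <= index < thres2):  R = R0 + k * index^2 * I
* high dynamic (index >= thres2, default 2g):   prediction only, no update

The filtered attitude rotates sensor data into the user frame
(Right-Forward-Up) with yaw forced to zero — the forward sensor axis is
mounted along the foot's forward direction, so only pitch/roll
misalignment needs cancelling.

Conventions: navigation frame is Right-Forward-Up; the gravity reference
is the specific force at rest, ``a_n = (0, 0, +g)``.  Euler angles use
the intrinsic Z-X-Y sequence: yaw about z (up), pitch about x (right),
roll about y (forward).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_core import Frame, ImuSample, ImuStream

__all__ = [
    "DynamicMode",
    "FilterConfig",
    "AttitudeState",
    "AttitudeFilter",
    "AttitudeTrack",
    "dynamic_index",
    "select_mode",
    "acc_residual",
    "measurement_matrix",
    "tilt_only",
    "to_user_frame",
    "project_stream",
    "run_filter",
]

G_DEFAULT = 9.80665


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


class DynamicMode(str, enum.Enum):
    STATIONARY = "stationary"
    LOW_ACCELERATION = "low_acceleration"
    HIGH_DYNAMIC = "high_dynamic"


@dataclass
class FilterConfig:
    """Tuning knobs of the attitude filter.

    tau_b : Gauss-Markov correlation time of the gyro bias [s].
    q_gyro : attitude-error process noise spectral density [rad^2/s]
        (per-sample gyro noise variance times the sample interval).
    q_bias : bias process noise spectral density [rad^2/s^3].
    g : local gravity magnitude [m/s^2].
    accel_noise_std : per-axis accelerometer sigma [m/s^2]; R0 = diag(sigma^2).
    thres1 : stationary threshold [m/s^2]; None -> 3*(sx^2+sy^2+sz^2)
        (the verbatim default rule; set ``thres1_rule='rms'`` for
        3*sqrt(sx^2+sy^2+sz^2) instead).
    thres2 : high-dynamic threshold [m/s^2]; None -> 2*g.
    k_scale : dimensionless gain of the low-acceleration R inflation.
    """

    tau_b: float = 100.0
    q_gyro: float = 1.25e-7
    q_bias: float = 1.0e-6
    g: float = G_DEFAULT
    accel_noise_std: np.ndarray = field(default_factory=lambda: np.full(3, 0.05))
    thres1: float | None = None
    thres1_rule: str = "variance"
    thres2: float | None = None
    k_scale: float = 1.0
    init_static_s: float = 0.5
    init_att_std_deg: float = 5.0
    init_bias_std: float = 0.05

    def __post_init__(self):
        self.accel_noise_std = np.asarray(self.accel_noise_std, float).reshape(3)
        if self.tau_b <= 0:
            raise ValueError("tau_b must be > 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if not (0.0 < self.thres1_eff < self.thres2_eff):
            raise ValueError("need 0 < thres1 < thres2")

    @property
    def R0(self) -> np.ndarray:
        return np.diag(self.accel_noise_std**2)

    @property
    def thres1_eff(self) -> float:
        if self.thres1 is not None:
            return self.thres1
        ss = float(np.sum(self.accel_noise_std**2))
        return 3.0 * np.sqrt(ss) if self.thres1_rule == "rms" else 3.0 * ss

    @property
    def thres2_eff(self) -> float:
        return 2.0 * self.g if self.thres2 is None else self.thres2


@dataclass
class AttitudeState:
    """Attitude estimate plus error-state covariance at time ``t``.

    ``rot`` is the body->navigation rotation (quaternion-backed).
    ``err_state`` holds [psi (rad, zeroed after feedback), eps_b (rad/s,
    the running gyro-bias estimate, retained between updates)].
    """

    rot: Rotation
    err_state: np.ndarray
    P: np.ndarray
    t: float

    @property
    def C_b_n(self) -> np.ndarray:
        return self.rot.as_matrix()

    @property
    def gyro_bias(self) -> np.ndarray:
        return self.err_state[3:]


def dynamic_index(accel: np.ndarray, g: float = G_DEFAULT) -> float:
    """Dynamic index ``| ||accel|| - g |`` separating rest from motion."""
    accel = np.asarray(accel, float)
    if not np.isfinite(accel).all():
        raise ValueError("non-finite accel")
    return abs(float(np.linalg.norm(accel)) - g)


def select_mode(index: float, cfg: FilterConfig) -> tuple[DynamicMode, np.ndarray | None]:
    """Classify the epoch and return the measurement covariance (None =
    skip the update entirely)."""
    if index < cfg.thres1_eff:
        return DynamicMode.STATIONARY, cfg.R0
    if index < cfg.thres2_eff:
        return DynamicMode.LOW_ACCELERATION, cfg.R0 + cfg.k_scale * index**2 * np.eye(3)
    return DynamicMode.HIGH_DYNAMIC, None


def acc_residual(accel_body: np.ndarray, state: AttitudeState,
                 g: float = G_DEFAULT) -> np.ndarray:
    """Body-frame acceleration residual: measurement minus gravity
    projected through the current attitude estimate."""
    a_n = np.array([0.0, 0.0, g])
    return np.asarray(accel_body, float) - state.C_b_n.T @ a_n


def measurement_matrix(state: AttitudeState, g: float = G_DEFAULT) -> np.ndarray:
    """3x6 Jacobian of the residual w.r.t. [psi, eps_b].

    The attitude block is ``C_n^b [a_n x]``; the bias does not enter the
    measurement, so the right 3x3 block is zero.
    """
    a_n = np.array([0.0, 0.0, g])
    H = np.zeros((3, 6))
    H[:, :3] = state.C_b_n.T @ _skew(a_n)
    return H


def tilt_only(rot: Rotation) -> Rotation:
    """Strip the yaw (rotation about up) component, keeping pitch/roll."""
    yaw, pitch, roll = rot.as_euler("ZXY")
    return Rotation.from_euler("ZXY", [0.0, pitch, roll])


def to_user_frame(sample: ImuSample, state: AttitudeState) -> ImuSample:
    """Rotate a sensor-frame sample into the Right-Forward-Up user frame
    using only the pitch/roll part of the current attitude."""
    if sample.frame is not Frame.SENSOR:
        raise ValueError(f"expected sensor-frame sample, got {sample.frame.value}")
    tilt = tilt_only(state.rot)
    return replace(sample, gyro=tilt.apply(sample.gyro),
                   accel=tilt.apply(sample.accel), frame=Frame.USER)


@dataclass
class AttitudeTrack:
    """Per-sample filter output for a whole stream."""

    t: np.ndarray
    quat: np.ndarray        # (n, 4) scalar-last body->nav
    euler_zxy: np.ndarray   # (n, 3) [yaw, pitch, roll] rad
    mode: list
    gyro_bias: np.ndarray   # (n, 3) running estimate

    def rotation(self, i: int) -> Rotation:
        return Rotation.from_quat(self.quat[i])


class AttitudeFilter:
    """Error-state Kalman filter over a 6-axis stream.

    Typical use::

        flt = AttitudeFilter(cfg)
        state = flt.initialize(stream)          # accel leveling on lead-in
        for sample, dt in ...:
            state, mode = flt.step(state, sample, dt)
    """

    def __init__(self, cfg: FilterConfig | None = None):
        self.cfg = cfg or FilterConfig()

    # -- initialisation ----------------------------------------------------

    def initialize(self, stream: ImuStream, t0: float | None = None) -> AttitudeState:
        """Accelerometer leveling on the assumed-static leading window;
        yaw = 0 by the user-frame definition."""
        cfg = self.cfg
        n0 = max(1, int(round(cfg.init_static_s * stream.rate_hz)))
        a_mean = stream.accel[:n0].mean(axis=0)
        norm = np.linalg.norm(a_mean)
        if norm < 1e-6:
            rot = Rotation.identity()
        else:
            rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [a_mean / norm])
        P = np.diag([np.deg2rad(cfg.init_att_std_deg)**2] * 3
                    + [cfg.init_bias_std**2] * 3)
        t_init = float(stream.t[0]) if t0 is None else t0
        return AttitudeState(rot=rot, err_state=np.zeros(6), P=P, t=t_init)

    # -- prediction --------------------------------------------------------

    def predict(self, state: AttitudeState, sample: ImuSample, dt: float) -> AttitudeState:
        """Integrate the bias-corrected angular rate and propagate the
        error-state covariance (omega_in^n treated as zero: stationary
        Earth, short windows)."""
        if dt <= 0 or not np.isfinite(dt):
            raise ValueError("dt must be positive and finite")
        if not np.isfinite(sample.gyro).all():
            raise ValueError("non-finite gyro")
        cfg = self.cfg
        w = sample.gyro - state.gyro_bias
        rot = state.rot * Rotation.from_rotvec(w * dt)

        C = state.rot.as_matrix()
        Phi = np.eye(6)
        # psi here is the nav-frame rotation taking truth to estimate with
        # the sign fixed by the +g gravity convention (see module docstring);
        # under it the bias couples as psi_dot = -C @ eps_b, with eps_b the
        # residual bias (true minus current estimate).
        Phi[:3, 3:] = -C * dt
        Phi[3:, 3:] *= 1.0 - dt / cfg.tau_b
        Q = np.zeros((6, 6))
        Q[:3, :3] = cfg.q_gyro * dt * np.eye(3)
        Q[3:, 3:] = cfg.q_bias * dt * np.eye(3)
        P = Phi @ state.P @ Phi.T + Q
        return AttitudeState(rot=rot, err_state=state.err_state.copy(), P=P,
                             t=state.t + dt)

    # -- update ------------------------------------------------------------

    def update(self, state: AttitudeState, residual: np.ndarray,
               H: np.ndarray, R: np.ndarray) -> AttitudeState:
        """Standard Kalman update; psi is fed back into the rotation
        (exact small-rotation correction, so orthonormality is preserved)
        and reset, the bias correction accumulates in err_state[3:]."""
        P = state.P
        S = H @ P @ H.T + R
        # S must be PSD; a Cholesky failure flags a numerically broken filter
        try:
            np.linalg.cholesky(S + 1e-15 * np.eye(3))
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("innovation covariance not PSD") from exc
        K = P @ H.T @ np.linalg.inv(S)
        dx = K @ np.asarray(residual, float)
        psi, dbias = dx[:3], dx[3:]
        rot = Rotation.from_rotvec(psi) * state.rot
        err = state.err_state.copy()
        err[:3] = 0.0
        err[3:] = err[3:] + dbias
        IKH = np.eye(6) - K @ H
        P_new = IKH @ P @ IKH.T + K @ R @ K.T  # Joseph form
        P_new = 0.5 * (P_new + P_new.T)
        return AttitudeState(rot=rot, err_state=err, P=P_new, t=state.t)

    # -- one epoch ---------------------------------------------------------

    def step(self, state: AttitudeState, sample: ImuSample,
             dt: float) -> tuple[AttitudeState, DynamicMode]:
        state = self.predict(state, sample, dt)
        idx = dynamic_index(sample.accel, self.cfg.g)
        mode, R = select_mode(idx, self.cfg)
        if R is not None:
            res = acc_residual(sample.accel, state, self.cfg.g)
            H = measurement_matrix(state, self.cfg.g)
            state = self.update(state, res, H, R)
        return state, mode

    # -- whole stream ------------------------------------------------------

    def run(self, stream: ImuStream) -> AttitudeTrack:
        n = len(stream)
        quat = np.empty((n, 4))
        euler = np.empty((n, 3))
        bias = np.empty((n, 3))
        modes: list[DynamicMode] = []
        state = self.initialize(stream)
        dt_nom = stream.dt_nominal
        for i in range(n):
            if i > 0:
                dt = float(stream.t[i] - stream.t[i - 1])
                state, mode = self.step(state, stream[i], dt if dt > 0 else dt_nom)
            else:
                mode = DynamicMode.STATIONARY
            quat[i] = state.rot.as_quat()
            euler[i] = state.rot.as_euler("ZXY")
            bias[i] = state.gyro_bias
            modes.append(mode)
        return AttitudeTrack(t=stream.t.copy(), quat=quat, euler_zxy=euler,
                             mode=modes, gyro_bias=bias)


def run_filter(stream: ImuStream, cfg: FilterConfig | None = None) -> AttitudeTrack:
    """Convenience wrapper: filter a whole sensor-frame stream."""
    return AttitudeFilter(cfg).run(stream)


def project_stream(stream: ImuStream, track: AttitudeTrack) -> ImuStream:
    """Rotate a sensor-frame stream into the user frame sample-by-sample
    using the tilt (pitch/roll) part of the filtered attitude."""
    if stream.frame is not Frame.SENSOR:
        raise ValueError("project_stream expects a sensor-frame stream")
    # tilt-only rotation == full rotation pre-multiplied by Rz(-yaw)
    yaw = track.euler_zxy[:, 0]
    rots = Rotation.from_euler("z", -yaw[:, None]) * Rotation.from_quat(track.quat)
    gyro = rots.apply(stream.gyro)
    accel = rots.apply(stream.accel)
    return ImuStream(t=stream.t, gyro=gyro, accel=accel, frame=Frame.USER,
                     rate_hz=stream.rate_hz)
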