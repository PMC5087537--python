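"""Physics-plausible synthetic gait-IMU generator.

Every stage of the pipeline is testable without recorded data: this
module synthesises labelled 6-axis streams for the five stepping motions
(jump, left, right, forward, backward) with the morphology the detector
relies on — four-phase gait cycles (stance, push-off, swing, heel-strike)
whose smoothed acceleration norm shows a push-off peak and a gentler
heel-strike bump, direction-dependent acceleration and displacement
signatures, wearer-to-wearer variation in strength and cadence, mounting
misalignment (pitch/roll), gyro bias and Gaussian sensor noise.

Construction of one cycle, in the user frame (Right-Forward-Up):

* horizontal: a raised-cosine push-off pulse along the motion's direction
  vector, balanced by a slower braking pulse during swing so the net
  horizontal velocity over the cycle is exactly zero;
* vertical: a push-off lift pulse, a near-free-fall dip during swing and
  a small heel-strike impact, balanced so the net vertical velocity is
  exactly zero;
* rotation: a single-axis gyro pulse pair (pitch for sagittal motions,
  roll for lateral ones) with exactly zero net rotation, so the mounting
  attitude is restored at the end of every cycle.

The true foot orientation is integrated from the synthetic angular rate
(closed form: each cycle rotates about one fixed axis), and specific
force is expressed in the (possibly misaligned) sensor frame through it,
so accelerometer and gyroscope are kinematically consistent.  Sensor
errors — bias, Gaussian noise, optionally scale-factor and
non-orthogonality through a CalibrationParams — are applied last, in the
sensor frame.

All pulse amplitudes live in :data:`GAIT_AMPLITUDES`; they are invented
plausible values, not measurements, and the pipeline's acceptance
properties are required to hold across a +/-50% amplitude sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .classify import MOTIONS, MotionLabel
from .imu_core import CalibrationParams, Frame, ImuStream, write_stream_csv

__all__ = [
    "GAIT_AMPLITUDES",
    "DIRECTION_VECTORS",
    "MotionProfile",
    "StepTruth",
    "LabelledStream",
    "simulate_static",
    "simulate_step",
    "simulate_session",
    "make_fixture_suite",
]

GRAVITY = 9.80665

#: user-frame direction of each motion (Right-Forward-Up)
DIRECTION_VECTORS = {
    MotionLabel.JUMP: np.array([0.0, 0.0, 1.0]),
    MotionLabel.LEFT: np.array([-1.0, 0.0, 0.0]),
    MotionLabel.RIGHT: np.array([1.0, 0.0, 0.0]),
    MotionLabel.FORWARD: np.array([0.0, 1.0, 0.0]),
    MotionLabel.BACKWARD: np.array([0.0, -1.0, 0.0]),
}

#: invented pulse amplitudes for a strength-1.0 wearer
GAIT_AMPLITUDES = {
    "push_horizontal": 9.0,     # m/s^2, along the direction vector (steps)
    "push_vertical_step": 4.5,  # m/s^2, lift component of a step push-off
    "push_vertical_jump": 13.0,  # m/s^2, jump take-off
    "heel_impact": 1.0,         # m/s^2, landing bump (below trigger threshold)
    "gyro_pulse": {             # rad/s and rotation axis per motion
        MotionLabel.FORWARD: (2.5, np.array([1.0, 0.0, 0.0])),
        MotionLabel.BACKWARD: (-2.5, np.array([1.0, 0.0, 0.0])),
        MotionLabel.LEFT: (-2.0, np.array([0.0, 1.0, 0.0])),
        MotionLabel.RIGHT: (2.0, np.array([0.0, 1.0, 0.0])),
        MotionLabel.JUMP: (1.2, np.array([1.0, 0.0, 0.0])),
    },
}


@dataclass
class MotionProfile:
    """One wearer's way of performing one motion.

    strength scales every pulse amplitude; cycle_duration is the full
    gait cycle [s]; phase_fractions (stance, push-off, swing,
    heel-strike) must be positive and sum to 1.  misalignment_deg is the
    (pitch, roll) mounting offset of the sensor on the shoe.
    """

    motion: MotionLabel
    strength: float = 1.0
    cycle_duration: float = 0.8
    phase_fractions: tuple = (0.25, 0.20, 0.35, 0.20)
    misalignment_deg: tuple = (0.0, 0.0)
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_noise_std: float = 0.05
    gyro_noise_std: float = 0.005
    rate_hz: float = 200.0

    def __post_init__(self):
        self.motion = MotionLabel(self.motion)
        self.gyro_bias = np.asarray(self.gyro_bias, float).reshape(3)
        pf = np.asarray(self.phase_fractions, float)
        if pf.size != 4 or (pf <= 0).any() or abs(pf.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must be 4 positive values summing to 1")

    @property
    def direction_vector(self) -> np.ndarray:
        return DIRECTION_VECTORS[self.motion]

    @property
    def mounting(self) -> Rotation:
        pitch, roll = np.deg2rad(self.misalignment_deg)
        return Rotation.from_euler("ZXY", [0.0, pitch, roll])


@dataclass
class StepTruth:
    """Ground truth for one simulated step."""

    motion: MotionLabel
    peak_index: int          # sample index of the push-off norm peak
    peak_time: float
    phase_bounds: dict       # phase name -> (start, stop) sample indices
    displacement: np.ndarray  # m, over the 31-sample window horizon


@dataclass
class LabelledStream:
    """Sensor-frame stream plus per-step ground truth."""

    stream: ImuStream
    truth: list
    misalignment_deg: tuple = (0.0, 0.0)

    def label_counts(self) -> dict:
        out: dict[MotionLabel, int] = {}
        for st in self.truth:
            out[st.motion] = out.get(st.motion, 0) + 1
        return out


def _raised_cosine(n_total: int, i0: int, i1: int) -> np.ndarray:
    """Smooth unit pulse supported on [i0, i1)."""
    env = np.zeros(n_total)
    m = i1 - i0
    if m > 0:
        env[i0:i1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(m) + 0.5) / m))
    return env


def _build_cycle(profile: MotionProfile):
    """User-frame truth for one cycle.

    Returns (specific force, angular rate, rotation axis, phase bounds,
    push-off peak index).  Net velocity and net rotation over the cycle
    are exactly zero (discrete sums balanced).
    """
    fs = profile.rate_hz
    n = int(round(profile.cycle_duration * fs))
    edges = np.round(np.cumsum((0.0,) + tuple(profile.phase_fractions)) * n).astype(int)
    bounds = {name: (int(edges[i]), int(edges[i + 1]))
              for i, name in enumerate(("stance", "push_off", "swing", "heel_strike"))}

    push = _raised_cosine(n, *bounds["push_off"])
    swing = _raised_cosine(n, *bounds["swing"])
    heel = _raised_cosine(n, *bounds["heel_strike"])

    s = profile.strength
    amp = GAIT_AMPLITUDES
    d = profile.direction_vector
    horizontal = d * np.array([1.0, 1.0, 0.0])

    a = np.zeros((n, 3))  # true kinematic acceleration, user frame
    # horizontal: push-off along d, braking spread over swing, zero net velocity
    a_h = amp["push_horizontal"] * s * float(np.linalg.norm(horizontal))
    if a_h > 0:
        brake = a_h * push.sum() / swing.sum()
        a += np.outer(a_h * push - brake * swing, horizontal)
    # vertical: lift + impact balanced by a swing dip (near free-fall)
    a_v = (amp["push_vertical_jump"] if profile.motion is MotionLabel.JUMP
           else amp["push_vertical_step"]) * s
    a_imp = amp["heel_impact"] * s
    dip = (a_v * push.sum() + a_imp * heel.sum()) / swing.sum()
    a[:, 2] += a_v * push + a_imp * heel - dip * swing

    f_user = a + np.array([0.0, 0.0, GRAVITY])  # specific force

    # single-axis rotation pulse pair, exactly zero net angle
    gamp, axis = amp["gyro_pulse"][profile.motion]
    gyro_scalar = gamp * s * (push - push.sum() / heel.sum() * heel)
    w_user = np.outer(gyro_scalar, axis)

    peak_index = int(np.argmax(np.linalg.norm(f_user, axis=1)))
    return f_user, w_user, axis, bounds, peak_index


def _window_displacement(a_user: np.ndarray, peak: int, fs: float) -> np.ndarray:
    """True displacement over the 31-sample window, trapezoidal double
    integral of the kinematic acceleration."""
    lo, hi = max(peak - 20, 0), min(peak + 11, a_user.shape[0])
    seg = a_user[lo:hi]
    dt = 1.0 / fs
    v = np.concatenate([np.zeros((1, 3)),
                        np.cumsum((seg[1:] + seg[:-1]) / 2 * dt, axis=0)])
    p = np.cumsum((v[1:] + v[:-1]) / 2 * dt, axis=0)
    return p[-1]


def _assemble(profiles: list[MotionProfile], pads_s: list[float], lead_in_s: float,
              misalignment_deg: tuple, gyro_bias: np.ndarray,
              accel_noise_std: float, gyro_noise_std: float,
              cal: CalibrationParams | None, rng: np.random.Generator,
              rate_hz: float) -> LabelledStream:
    """Concatenate stance padding and cycles, rotate into the sensor
    frame through the integrated true orientation, then add sensor
    errors.  Noise is drawn in one block after all content, so identical
    seeds give identical draws regardless of the mounting."""
    fs = rate_hz
    f_parts, w_parts, rv_parts = [], [], []
    truth: list[StepTruth] = []

    def stance(dur_s):
        m = int(round(dur_s * fs))
        f_parts.append(np.tile([0.0, 0.0, GRAVITY], (m, 1)))
        w_parts.append(np.zeros((m, 3)))
        rv_parts.append(np.zeros((m, 3)))
        return m

    offset = stance(lead_in_s)
    for profile, pad in zip(profiles, pads_s):
        f_u, w_u, axis, bounds, peak = _build_cycle(profile)
        a_u = f_u - np.array([0.0, 0.0, GRAVITY])
        truth.append(StepTruth(
            motion=profile.motion,
            peak_index=offset + peak,
            peak_time=(offset + peak) / fs,
            phase_bounds={k: (offset + i0, offset + i1)
                          for k, (i0, i1) in bounds.items()},
            displacement=_window_displacement(a_u, peak, fs)))
        f_parts.append(f_u)
        w_parts.append(w_u)
        # closed-form orientation: the cycle rotates about one fixed axis,
        # angle(t) = integral of the scalar rate (rectangle rule, lagged
        # one sample to mirror how a strapdown integrator consumes it)
        scal = w_u @ axis
        angle = (np.cumsum(scal) - scal) / fs
        rv_parts.append(np.outer(angle, axis))
        offset += f_u.shape[0]
        offset += stance(pad)

    f_user = np.vstack(f_parts)
    w_user = np.vstack(w_parts)
    rotvec = np.vstack(rv_parts)
    n = f_user.shape[0]

    pitch, roll = np.deg2rad(misalignment_deg)
    mount = Rotation.from_euler("ZXY", [0.0, pitch, roll])
    C_u_b = (Rotation.from_rotvec(rotvec) * mount).inv()  # user -> body, per sample
    f_body = C_u_b.apply(f_user)
    w_body = C_u_b.apply(w_user)

    gyro = w_body + gyro_bias + rng.normal(0.0, gyro_noise_std, (n, 3))
    accel = f_body + rng.normal(0.0, accel_noise_std, (n, 3))
    if cal is not None:
        gyro = gyro + cal.gyro_bias + gyro @ (cal.gyro_scale + cal.gyro_nonorth).T
        accel = accel + cal.accel_bias + accel @ (cal.accel_scale + cal.accel_nonorth).T

    stream = ImuStream(t=np.arange(n) / fs, gyro=gyro, accel=accel,
                       frame=Frame.SENSOR, rate_hz=fs)
    return LabelledStream(stream=stream, truth=truth,
                          misalignment_deg=tuple(misalignment_deg))


def simulate_static(duration_s: float, seed: int = 0,
                    misalignment_deg: tuple = (0.0, 0.0),
                    gyro_bias=(0.0, 0.0, 0.0),
                    accel_noise_std: float = 0.05,
                    gyro_noise_std: float = 0.005,
                    rate_hz: float = 200.0) -> LabelledStream:
    """A stance-only stream: the noise-free specific force has norm g
    everywhere and the gyro reads its bias."""
    rng = np.random.default_rng(seed)
    return _assemble([], [], duration_s, misalignment_deg,
                     np.asarray(gyro_bias, float), accel_noise_std,
                     gyro_noise_std, None, rng, rate_hz)


def simulate_step(profile: MotionProfile, seed: int = 0,
                  lead_in_s: float = 0.5, tail_s: float = 0.3,
                  cal: CalibrationParams | None = None) -> LabelledStream:
    """One labelled gait cycle with a stance lead-in (for filter
    initialisation) and tail; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return _assemble([profile], [tail_s], lead_in_s, profile.misalignment_deg,
                     profile.gyro_bias, profile.accel_noise_std,
                     profile.gyro_noise_std, cal, rng, profile.rate_hz)


def simulate_session(motions, seed: int = 0,
                     strength_range: tuple = (0.7, 1.3),
                     cycle_range: tuple = (0.7, 0.95),
                     pad_range: tuple = (0.2, 0.4),
                     lead_in_s: float = 2.0,
                     misalignment_deg: tuple = (0.0, 0.0),
                     gyro_bias=None,
                     accel_noise_std: float = 0.05,
                     gyro_noise_std: float = 0.005,
                     cal: CalibrationParams | None = None,
                     rate_hz: float = 200.0,
                     strength_scale: float = 1.0) -> LabelledStream:
    """A labelled multi-step session with wearer variation.

    ``motions`` is a sequence of MotionLabel values (one per step).  Each
    step's strength and cycle duration are jittered within the stated
    ranges — emulating heavy/slight, fast/slow, large/small performances.
    ``gyro_bias=None`` draws a session bias ~ N(0, 0.01 rad/s) per axis.
    The content draws are independent of the mounting, so two sessions
    with the same seed and different ``misalignment_deg`` contain the
    identical user-frame truth.
    """
    motions = [MotionLabel(m) for m in motions]
    if not motions:
        raise ValueError("need at least one motion")
    rng = np.random.default_rng(seed)
    if gyro_bias is None:
        gyro_bias = rng.normal(0.0, 0.01, 3)
    else:
        gyro_bias = np.asarray(gyro_bias, float)
    profiles, pads = [], []
    for m in motions:
        profiles.append(MotionProfile(
            m,
            strength=rng.uniform(*strength_range) * strength_scale,
            cycle_duration=rng.uniform(*cycle_range),
            misalignment_deg=misalignment_deg,
            rate_hz=rate_hz))
        pads.append(rng.uniform(*pad_range))
    return _assemble(profiles, pads, lead_in_s, misalignment_deg, gyro_bias,
                     accel_noise_std, gyro_noise_std, cal, rng, rate_hz)


def make_fixture_suite(seed: int, outdir) -> dict:
    """Emit the small CSV fixtures used across module tests: a static
    stream, one single-step stream per motion, and a mixed session.
    Returns {name: (csv path, LabelledStream)}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}

    def emit(name, ls):
        path = outdir / f"{name}.csv"
        write_stream_csv(ls.stream, path)
        meta = [{"motion": st.motion.value, "peak_index": st.peak_index,
                 "peak_time": st.peak_time,
                 "phase_bounds": {k: list(v) for k, v in st.phase_bounds.items()},
                 "displacement": st.displacement.tolist()} for st in ls.truth]
        (outdir / f"{name}.truth.json").write_text(json.dumps(meta, indent=2))
        out[name] = (path, ls)

    emit("static", simulate_static(5.0, seed=seed))
    for i, m in enumerate(MOTIONS):
        emit(f"step_{m.value}", simulate_step(MotionProfile(m), seed=seed + 1 + i))
    mixed = [m for m in MOTIONS for _ in range(3)]
    emit("mixed_session", simulate_session(mixed, seed=seed + 100))
    return out
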