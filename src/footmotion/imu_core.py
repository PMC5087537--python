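"""Inertial data model and deterministic sensor-error compensation.

A foot-mounted MEMS IMU delivers a 6-axis stream (3-axis gyroscope in
rad/s, 3-axis accelerometer specific force in m/s^2) at a nominal 200 Hz.
Before any attitude estimation or feature extraction, the deterministic
part of the sensor error — bias, linear scale-factor error and axis
non-orthogonality — is removed using the standard measurement model

    x_meas = x + b + (S + N) @ x + noise

which is inverted exactly as ``x = (I + S + N)^-1 (x_meas - b)``.  The
stochastic term is left in the signal; it is handled downstream by
smoothing and by the attitude filter's measurement noise model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Frame",
    "ImuSample",
    "ImuStream",
    "CalibrationParams",
    "CalibrationError",
    "FrameError",
    "compensate",
    "compensate_stream",
    "forward_model",
    "read_stream_csv",
    "write_stream_csv",
    "load_calibration",
    "save_calibration",
]

STREAM_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]


class Frame(str, enum.Enum):
    """Coordinate frame an inertial measurement is expressed in."""

    SENSOR = "sensor"        # shoe-mounted axes, arbitrary pitch/roll
    USER = "user"            # Right(x)-Forward(y)-Up(z), yaw-free
    NAVIGATION = "navigation"


class CalibrationError(ValueError):
    """Raised when calibration parameters cannot be inverted."""


class FrameError(ValueError):
    """Raised when an operation receives data in the wrong frame."""


def _vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


def _mat3(x) -> np.ndarray:
    m = np.asarray(x, dtype=float).reshape(3, 3)
    return m


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped 6-axis measurement in a declared frame."""

    t: float
    gyro: np.ndarray   # rad/s
    accel: np.ndarray  # m/s^2, specific force
    frame: Frame = Frame.SENSOR

    def __post_init__(self):
        object.__setattr__(self, "gyro", _vec3(self.gyro))
        object.__setattr__(self, "accel", _vec3(self.accel))
        object.__setattr__(self, "frame", Frame(self.frame))
        if not (np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValueError("non-finite IMU sample")


@dataclass
class ImuStream:
    """An ordered 6-axis stream sharing one frame tag.

    Stored column-wise (``t``: (n,), ``gyro``/``accel``: (n, 3)) — the
    natural layout for vectorised processing; ``__getitem__`` yields
    :class:`ImuSample` views for per-sample consumers.
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    frame: Frame = Frame.SENSOR
    rate_hz: float = 200.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        n = self.t.size
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(n, 3)
        self.accel = np.asarray(self.accel, dtype=float).reshape(n, 3)
        self.frame = Frame(self.frame)
        if n > 1:
            dt = np.diff(self.t)
            if not (dt > 0).all():
                raise ValueError("timestamps must be strictly increasing")
            nominal = 1.0 / self.rate_hz
            if abs(np.median(dt) - nominal) > 0.1 * nominal:
                raise ValueError(
                    f"median sample interval {np.median(dt):.6g} s deviates >10% "
                    f"from nominal {nominal:.6g} s"
                )
        if not (np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValueError("non-finite values in stream")

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(t=float(self.t[i]), gyro=self.gyro[i], accel=self.accel[i],
                         frame=self.frame)

    @property
    def dt_nominal(self) -> float:
        return 1.0 / self.rate_hz


@dataclass
class CalibrationParams:
    """Deterministic error parameters for both triads plus noise magnitudes.

    ``gyro_scale``/``gyro_nonorth`` (and the accelerometer counterparts)
    are the S and N matrices of the forward model; they are combined as
    ``I + S + N`` which must be invertible.  Noise standard deviations are
    per-sample sigmas; the accelerometer ones also parameterise the
    attitude filter's measurement covariance and its stationary threshold.
    """

    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_scale: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    accel_scale: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    gyro_nonorth: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    accel_nonorth: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    gyro_noise_std: np.ndarray = field(default_factory=lambda: np.full(3, 0.005))
    accel_noise_std: np.ndarray = field(default_factory=lambda: np.full(3, 0.05))

    def __post_init__(self):
        self.gyro_bias = _vec3(self.gyro_bias)
        self.accel_bias = _vec3(self.accel_bias)
        self.gyro_scale = _mat3(self.gyro_scale)
        self.accel_scale = _mat3(self.accel_scale)
        self.gyro_nonorth = _mat3(self.gyro_nonorth)
        self.accel_nonorth = _mat3(self.accel_nonorth)
        self.gyro_noise_std = _vec3(self.gyro_noise_std)
        self.accel_noise_std = _vec3(self.accel_noise_std)
        if (self.gyro_noise_std < 0).any() or (self.accel_noise_std < 0).any():
            raise ValueError("noise standard deviations must be >= 0")

    def _combined(self, which: str) -> np.ndarray:
        if which == "gyro":
            m = np.eye(3) + self.gyro_scale + self.gyro_nonorth
        else:
            m = np.eye(3) + self.accel_scale + self.accel_nonorth
        if abs(np.linalg.det(m)) < 1e-12:
            raise CalibrationError(f"(I + S + N) singular for {which} triad")
        return m

    @property
    def gyro_matrix(self) -> np.ndarray:
        return self._combined("gyro")

    @property
    def accel_matrix(self) -> np.ndarray:
        return self._combined("accel")


def forward_model(sample: ImuSample, cal: CalibrationParams,
                  rng: np.random.Generator | None = None) -> ImuSample:
    """Apply the sensor error model to a true sample (simulation aid).

    Produces ``x_meas = x + b + (S + N) x (+ noise)``; the exact inverse
    of :func:`compensate` when ``rng`` is None.
    """
    gyro = sample.gyro + cal.gyro_bias + (cal.gyro_scale + cal.gyro_nonorth) @ sample.gyro
    accel = sample.accel + cal.accel_bias + (cal.accel_scale + cal.accel_nonorth) @ sample.accel
    if rng is not None:
        gyro = gyro + rng.normal(0.0, cal.gyro_noise_std)
        accel = accel + rng.normal(0.0, cal.accel_noise_std)
    return replace(sample, gyro=gyro, accel=accel)


def compensate(raw: ImuSample, cal: CalibrationParams) -> ImuSample:
    """Remove deterministic sensor errors from one sensor-frame sample.

    Exact inversion ``x = (I + S + N)^-1 (x_meas - b)`` for each triad;
    the stochastic noise term is left untouched.  The output stays in the
    sensor frame (compensation does not re-orient the axes).
    """
    if raw.frame is not Frame.SENSOR:
        raise FrameError(f"compensate expects sensor-frame input, got {raw.frame.value}")
    gyro = np.linalg.solve(cal.gyro_matrix, raw.gyro - cal.gyro_bias)
    accel = np.linalg.solve(cal.accel_matrix, raw.accel - cal.accel_bias)
    return replace(raw, gyro=gyro, accel=accel)


def compensate_stream(stream: ImuStream, cal: CalibrationParams) -> ImuStream:
    """Vectorised :func:`compensate` over a whole sensor-frame stream."""
    if stream.frame is not Frame.SENSOR:
        raise FrameError(f"compensate expects sensor-frame input, got {stream.frame.value}")
    gyro = np.linalg.solve(cal.gyro_matrix, (stream.gyro - cal.gyro_bias).T).T
    accel = np.linalg.solve(cal.accel_matrix, (stream.accel - cal.accel_bias).T).T
    return ImuStream(t=stream.t, gyro=gyro, accel=accel, frame=Frame.SENSOR,
                     rate_hz=stream.rate_hz)


# ---------------------------------------------------------------------------
# CSV stream format: header `t,gx,gy,gz,ax,ay,az`, SI units, '.' decimal.


def read_stream_csv(path, frame: Frame = Frame.SENSOR, rate_hz: float = 200.0,
                    gyro_in_deg: bool = False) -> ImuStream:
    """Read a stream CSV.  ``gyro_in_deg`` converts deg/s columns on ingest."""
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream CSV missing columns: {missing}")
    gyro = df[["gx", "gy", "gz"]].to_numpy(float)
    if gyro_in_deg:
        gyro = np.deg2rad(gyro)
    return ImuStream(t=df["t"].to_numpy(float), gyro=gyro,
                     accel=df[["ax", "ay", "az"]].to_numpy(float),
                     frame=frame, rate_hz=rate_hz)


def write_stream_csv(stream: ImuStream, path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.gyro, stream.accel]),
        columns=STREAM_COLUMNS,
    )
    # %.17g preserves doubles exactly on round-trip
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Calibration config block (YAML key tree)


def _cal_to_tree(cal: CalibrationParams) -> dict:
    return {
        "gyro": {
            "bias": cal.gyro_bias.tolist(),
            "scale": cal.gyro_scale.tolist(),
            "nonorth": cal.gyro_nonorth.tolist(),
        },
        "accel": {
            "bias": cal.accel_bias.tolist(),
            "scale": cal.accel_scale.tolist(),
            "nonorth": cal.accel_nonorth.tolist(),
        },
        "noise": {
            "gyro_std": cal.gyro_noise_std.tolist(),
            "accel_std": cal.accel_noise_std.tolist(),
        },
    }


def _cal_from_tree(tree: dict) -> CalibrationParams:
    cal = CalibrationParams()
    g = tree.get("gyro", {})
    a = tree.get("accel", {})
    n = tree.get("noise", {})
    kw = {}
    if "bias" in g:
        kw["gyro_bias"] = g["bias"]
    if "scale" in g:
        kw["gyro_scale"] = g["scale"]
    if "nonorth" in g:
        kw["gyro_nonorth"] = g["nonorth"]
    if "bias" in a:
        kw["accel_bias"] = a["bias"]
    if "scale" in a:
        kw["accel_scale"] = a["scale"]
    if "nonorth" in a:
        kw["accel_nonorth"] = a["nonorth"]
    if "gyro_std" in n:
        kw["gyro_noise_std"] = n["gyro_std"]
    if "accel_std" in n:
        kw["accel_noise_std"] = n["accel_std"]
    known = {"gyro": {"bias", "scale", "nonorth"}, "accel": {"bias", "scale", "nonorth"},
             "noise": {"gyro_std", "accel_std"}}
    for section, keys in known.items():
        unknown = set(tree.get(section, {})) - keys
        if unknown:
            raise ValueError(f"unknown calibration keys in '{section}': {sorted(unknown)}")
    unknown = set(tree) - set(known)
    if unknown:
        raise ValueError(f"unknown calibration sections: {sorted(unknown)}")
    return CalibrationParams(**kw) if kw else cal


def load_calibration(path) -> CalibrationParams:
    with open(path) as fh:
        tree = yaml.safe_load(fh) or {}
    return _cal_from_tree(tree)


def save_calibration(cal: CalibrationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_cal_to_tree(cal), fh, sort_keys=False)
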