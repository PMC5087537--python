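"""Per-window feature extraction.

For each 31-sample user-frame window the classifier sees:

* per-axis mean and population variance of accelerometer and gyroscope,
* per-axis signal magnitude area (SMA) of the accelerometer,
  ``sum |x_i| * dt`` — an activity-intensity measure,
* the short-horizon displacement from double trapezoidal integration of
  gravity-removed acceleration with zero initial velocity/position and
  zero azimuth (a foot travels centimetres within 0.155 s; MEMS drift is
  negligible on that horizon),
* ratio features — each of the displacement, accelerometer-mean,
  accelerometer-variance and SMA triples divided by its Euclidean norm —
  which make the signature invariant to how hard the wearer steps.

The feature order is fixed and versioned (:data:`FEATURE_NAMES`,
:data:`FEATURE_SCHEMA_VERSION`); trained models refuse vectors from a
different schema.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .segmentation import SegmentWindow

__all__ = [
    "FEATURE_SCHEMA_VERSION",
    "FEATURE_NAMES",
    "GRAVITY",
    "mean_variance",
    "sma",
    "position_change",
    "ratio",
    "build_feature_vector",
    "feature_matrix",
]

GRAVITY = 9.80665

FEATURE_SCHEMA_VERSION = "1"

_AXES = ("x", "y", "z")
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"accel_mean_{a}" for a in _AXES]
    + [f"accel_var_{a}" for a in _AXES]
    + [f"gyro_mean_{a}" for a in _AXES]
    + [f"gyro_var_{a}" for a in _AXES]
    + [f"accel_sma_{a}" for a in _AXES]
    + [f"disp_{a}" for a in _AXES]
    + [f"ratio_disp_{a}" for a in _AXES]
    + [f"ratio_accel_mean_{a}" for a in _AXES]
    + [f"ratio_accel_var_{a}" for a in _AXES]
    + [f"ratio_sma_{a}" for a in _AXES]
)


def mean_variance(window: SegmentWindow) -> dict[str, np.ndarray]:
    """Per-axis mean and population variance (divide by N) for both triads."""
    out = {}
    for name, data in (("accel", window.accel), ("gyro", window.gyro)):
        out[f"{name}_mean"] = data.mean(axis=0)
        out[f"{name}_var"] = data.var(axis=0)  # ddof=0: population form
    return out


def sma(window: SegmentWindow) -> np.ndarray:
    """Per-axis signal magnitude area of the accelerometer, trapezoidal
    ``integral |x| dt`` over the window [m/s]."""
    return np.trapezoid(np.abs(window.accel), x=window.t, axis=0)


def position_change(window: SegmentWindow, g: float = GRAVITY) -> np.ndarray:
    """Displacement over the window horizon [m].

    Window samples are already in the user frame (tilt corrected, zero
    azimuth), so navigation-frame acceleration is the specific force
    minus gravity; v and p start at zero.
    """
    a_n = window.accel - np.array([0.0, 0.0, g])
    v = cumulative_trapezoid(a_n, x=window.t, axis=0, initial=0.0)
    p = cumulative_trapezoid(v, x=window.t, axis=0, initial=0.0)
    return p[-1]


def ratio(triple: np.ndarray) -> np.ndarray:
    """Each value divided by the norm of the 3-axis triple.

    A zero-norm triple returns (0, 0, 0): degenerate windows must not
    kill a real-time stream.
    """
    triple = np.asarray(triple, float).reshape(3)
    norm = float(np.linalg.norm(triple))
    if norm == 0.0:
        return np.zeros(3)
    return triple / norm


def build_feature_vector(window: SegmentWindow) -> np.ndarray:
    """Deterministic, fixed-order feature vector (see FEATURE_NAMES)."""
    mv = mean_variance(window)
    s = sma(window)
    d = position_change(window)
    parts = [
        mv["accel_mean"], mv["accel_var"], mv["gyro_mean"], mv["gyro_var"],
        s, d,
        ratio(d), ratio(mv["accel_mean"]), ratio(mv["accel_var"]), ratio(s),
    ]
    fv = np.concatenate(parts)
    assert fv.size == len(FEATURE_NAMES)
    return fv


def feature_matrix(windows: list[SegmentWindow]) -> np.ndarray:
    """Stack feature vectors for a list of windows into (n, n_features)."""
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([build_feature_vector(w) for w in windows])
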