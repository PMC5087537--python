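"""Peak-triggered gait segmentation.

Each gait cycle produces two bumps in the norm of the user-frame
acceleration: a push-off peak as the foot leaves the ground and a
heel-strike peak as it lands.  The push-off peak is a reliable trigger —
it is present in every cycle regardless of the wearer — so classification
runs once per detected peak instead of on sliding windows.

The detector works on a causally smoothed norm (moving average of the
previous N samples, which shifts peaks right by about (N-1)/2 samples; the
constant group delay is accepted, as it does not affect recognition).  A
detected peak cuts a fixed 31-sample window: 20 samples before the peak,
the peak itself, and 10 after — 0.15 s at 200 Hz, which is the decision
latency of the system.

Offline (:func:`segment_stream`) and online (:class:`StreamingSegmenter`)
paths are implemented independently and are contract-equal: the same
stream yields the identical window set either way.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .imu_core import Frame, ImuStream

__all__ = [
    "SmootherConfig",
    "SegmentWindow",
    "WindowUnavailable",
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "WINDOW_LEN",
    "smooth_norm",
    "detect_peaks",
    "extract_window",
    "segment_stream",
    "StreamingSegmenter",
]

PRE_SAMPLES = 20
POST_SAMPLES = 10
WINDOW_LEN = PRE_SAMPLES + POST_SAMPLES + 1  # 31


@dataclass
class SmootherConfig:
    """Moving-average smoother and peak-acceptance parameters.

    window_n : moving-average length N in samples (50 ms at 200 Hz).
    min_peak_height : smoothed-norm threshold [m/s^2]; the default
        g + 2 admits push-off peaks while rejecting the gentler
        heel-strike bump and stance noise.
    refractory : minimum sample separation between accepted peaks
        (0.2 s at 200 Hz), suppressing multi-peak push-off phases.
    """

    window_n: int = 10
    min_peak_height: float = 9.80665 + 2.0
    refractory: int = 40

    def __post_init__(self):
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    @property
    def group_delay(self) -> int:
        """Nominal lag of the causal smoother in samples."""
        return (self.window_n - 1) // 2


class WindowUnavailable(ValueError):
    """Peak too close to a stream edge to cut the 31-sample window."""


@dataclass
class SegmentWindow:
    """The 31-sample user-frame slice around one push-off peak.

    ``peak_index_local`` is always 20 (0-based).  ``trigger_index`` is the
    position of the peak in the source stream; ``attitude_at_peak`` is the
    body->navigation rotation matrix snapshot, when available.
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    peak_time: float
    trigger_index: int
    rate_hz: float = 200.0
    peak_index_local: int = PRE_SAMPLES
    attitude_at_peak: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float).reshape(-1)
        if self.t.size != WINDOW_LEN:
            raise ValueError(f"window must hold exactly {WINDOW_LEN} samples")
        self.gyro = np.asarray(self.gyro, float).reshape(WINDOW_LEN, 3)
        self.accel = np.asarray(self.accel, float).reshape(WINDOW_LEN, 3)
        if self.peak_index_local != PRE_SAMPLES:
            raise ValueError(f"peak must sit at local index {PRE_SAMPLES}")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("window samples must be contiguous in time")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.t)


def smooth_norm(stream: ImuStream, cfg: SmootherConfig) -> np.ndarray:
    """Causal moving average of the acceleration norm.

    Sample i is the mean of the norms at [i-N+1 .. i]; the first N-1
    samples average the available prefix.
    """
    norm = np.linalg.norm(stream.accel, axis=1)
    n = norm.size
    N = cfg.window_n
    csum = np.concatenate([[0.0], np.cumsum(norm)])
    idx = np.arange(n)
    lo = np.maximum(idx - N + 1, 0)
    return (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)


def detect_peaks(smoothed: np.ndarray, cfg: SmootherConfig) -> list[int]:
    """Indices i with s[i-1] < s[i] >= s[i+1], s[i] >= min_peak_height and
    at least ``refractory`` samples after the previously accepted peak.

    Sequential scan — a peak at index i is decidable once sample i+1 has
    arrived, matching the online contract.
    """
    s = np.asarray(smoothed, float)
    peaks: list[int] = []
    last = None
    for i in range(1, s.size - 1):
        if s[i - 1] < s[i] >= s[i + 1] and s[i] >= cfg.min_peak_height:
            if last is None or i - last >= cfg.refractory:
                peaks.append(i)
                last = i
    return peaks


def extract_window(stream: ImuStream, peak_idx: int,
                   attitude_at_peak: np.ndarray | None = None) -> SegmentWindow:
    """Cut the closed window [peak-20, peak+10] around an accepted peak."""
    if peak_idx < PRE_SAMPLES or peak_idx + POST_SAMPLES >= len(stream):
        raise WindowUnavailable(
            f"peak at {peak_idx} needs {PRE_SAMPLES} samples before and "
            f"{POST_SAMPLES} after (stream length {len(stream)})")
    lo, hi = peak_idx - PRE_SAMPLES, peak_idx + POST_SAMPLES + 1
    return SegmentWindow(
        t=stream.t[lo:hi], gyro=stream.gyro[lo:hi], accel=stream.accel[lo:hi],
        peak_time=float(stream.t[peak_idx]), trigger_index=peak_idx,
        rate_hz=stream.rate_hz, attitude_at_peak=attitude_at_peak)


def segment_stream(stream: ImuStream, cfg: SmootherConfig | None = None,
                   attitudes: np.ndarray | None = None) -> list[SegmentWindow]:
    """Offline segmentation: smooth, detect, cut.  Peaks too close to the
    stream edges are dropped (logged upstream as window-unavailable).

    ``attitudes`` optionally supplies per-sample 3x3 rotation snapshots.
    """
    if stream.frame is not Frame.USER:
        raise ValueError("segmentation expects a user-frame stream")
    cfg = cfg or SmootherConfig()
    smoothed = smooth_norm(stream, cfg)
    windows = []
    for p in detect_peaks(smoothed, cfg):
        try:
            att = None if attitudes is None else attitudes[p]
            windows.append(extract_window(stream, p, attitude_at_peak=att))
        except WindowUnavailable:
            continue
    return windows


class StreamingSegmenter:
    """Online counterpart of :func:`segment_stream`.

    Feed samples one at a time; a completed :class:`SegmentWindow` is
    returned POST_SAMPLES samples after its trigger peak (plus one sample
    to confirm the local maximum), matching the offline result exactly.
    """

    def __init__(self, cfg: SmootherConfig | None = None, rate_hz: float = 200.0):
        self.cfg = cfg or SmootherConfig()
        self.rate_hz = rate_hz
        self._norms: deque[float] = deque(maxlen=self.cfg.window_n)
        # history must cover PRE_SAMPLES back from a peak confirmed one
        # sample late, plus the POST_SAMPLES wait
        self._hist: deque[tuple[float, np.ndarray, np.ndarray, np.ndarray | None]] = deque(
            maxlen=PRE_SAMPLES + POST_SAMPLES + 2)
        self._s_prev2: float | None = None
        self._s_prev: float | None = None
        self._i = -1
        self._last_peak: int | None = None
        self._pending: list[int] = []

    def push(self, t: float, gyro: np.ndarray, accel: np.ndarray,
             attitude: np.ndarray | None = None) -> SegmentWindow | None:
        """Ingest one user-frame sample; return a window if one completes."""
        self._i += 1
        i = self._i
        self._norms.append(float(np.linalg.norm(accel)))
        s = sum(self._norms) / len(self._norms)
        self._hist.append((float(t), np.asarray(gyro, float).copy(),
                           np.asarray(accel, float).copy(), attitude))

        # confirm a peak at i-1 now that sample i bounds it on the right
        if self._s_prev2 is not None:
            if (self._s_prev2 < self._s_prev >= s
                    and self._s_prev >= self.cfg.min_peak_height):
                p = i - 1
                if self._last_peak is None or p - self._last_peak >= self.cfg.refractory:
                    self._last_peak = p
                    if p >= PRE_SAMPLES:
                        self._pending.append(p)
        self._s_prev2, self._s_prev = self._s_prev, s

        if self._pending and i - self._pending[0] >= POST_SAMPLES:
            p = self._pending.pop(0)
            offset = i - p  # == POST_SAMPLES
            rows = list(self._hist)[len(self._hist) - (PRE_SAMPLES + offset + 1):]
            rows = rows[:WINDOW_LEN]
            ts = np.array([r[0] for r in rows])
            gy = np.array([r[1] for r in rows])
            ac = np.array([r[2] for r in rows])
            att = rows[PRE_SAMPLES][3]
            return SegmentWindow(t=ts, gyro=gy, accel=ac,
                                 peak_time=float(rows[PRE_SAMPLES][0]),
                                 trigger_index=p, rate_hz=self.rate_hz,
                                 attitude_at_peak=att)
        return None

    def run(self, stream: ImuStream,
            attitudes: np.ndarray | None = None) -> list[SegmentWindow]:
        """Replay a whole stream through the online path."""
        out = []
        for i in range(len(stream)):
            att = None if attitudes is None else attitudes[i]
            w = self.push(stream.t[i], stream.gyro[i], stream.accel[i], att)
            if w is not None:
                out.append(w)
        return out
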