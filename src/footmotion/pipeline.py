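"""End-to-end plumbing: raw sensor stream -> motion events.

The processing chain is: error compensation (imu_core) -> attitude
filtering and user-frame projection (attitude) -> peak-triggered
segmentation (segmentation) -> feature extraction (features) ->
classifier bank (classify).  This module wires the stages, builds
labelled feature datasets from synthetic sessions, and runs the
streaming recogniser that emits one event per detected step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attitude import AttitudeFilter, AttitudeTrack, FilterConfig, project_stream
from .classify import ClassifierBank, MotionLabel
from .features import FEATURE_NAMES, feature_matrix
from .imu_core import CalibrationParams, ImuStream, compensate_stream
from .segmentation import (POST_SAMPLES, SegmentWindow, SmootherConfig,
                           StreamingSegmenter, segment_stream)
from .synthetic import LabelledStream

__all__ = [
    "MotionEvent",
    "extract_windows",
    "build_dataset",
    "match_windows_to_truth",
    "run_stream",
]


@dataclass(frozen=True)
class MotionEvent:
    """One recognised step: when, what, how confident, how late."""

    t: float
    label: MotionLabel
    score: float
    latency_samples: int

    def as_dict(self) -> dict:
        return {"t": self.t, "label": self.label.value, "score": self.score,
                "latency_samples": self.latency_samples}


def extract_windows(stream: ImuStream,
                    cal: CalibrationParams | None = None,
                    filter_cfg: FilterConfig | None = None,
                    smoother_cfg: SmootherConfig | None = None,
                    ) -> tuple[list[SegmentWindow], AttitudeTrack]:
    """Run compensation, attitude filtering, user-frame projection and
    segmentation on a raw sensor-frame stream."""
    if cal is not None:
        stream = compensate_stream(stream, cal)
    track = AttitudeFilter(filter_cfg).run(stream)
    user = project_stream(stream, track)
    attitudes = np.array([track.rotation(i).as_matrix() for i in range(len(user))])
    windows = segment_stream(user, smoother_cfg, attitudes=attitudes)
    return windows, track


def match_windows_to_truth(windows: list[SegmentWindow], labelled: LabelledStream,
                           smoother_cfg: SmootherConfig | None = None,
                           tol_samples: int = 5) -> list[tuple[SegmentWindow, MotionLabel]]:
    """Pair detected windows with ground-truth steps.

    The detector reports peaks on the causally smoothed norm, which lags
    the true peak by the smoother's constant group delay; that delay is
    removed before applying the +/- tolerance.
    """
    cfg = smoother_cfg or SmootherConfig()
    lag = cfg.group_delay
    pairs = []
    for w in windows:
        det = w.trigger_index - lag
        best, best_d = None, None
        for st in labelled.truth:
            d = abs(det - st.peak_index)
            if best_d is None or d < best_d:
                best, best_d = st, d
        if best is not None and best_d <= tol_samples:
            pairs.append((w, best.motion))
    return pairs


def build_dataset(labelled: LabelledStream,
                  cal: CalibrationParams | None = None,
                  filter_cfg: FilterConfig | None = None,
                  smoother_cfg: SmootherConfig | None = None,
                  tol_samples: int = 5) -> tuple[np.ndarray, list[MotionLabel]]:
    """Feature matrix and labels from a labelled synthetic session."""
    windows, _ = extract_windows(labelled.stream, cal, filter_cfg, smoother_cfg)
    pairs = match_windows_to_truth(windows, labelled, smoother_cfg, tol_samples)
    if not pairs:
        return np.empty((0, len(FEATURE_NAMES))), []
    X = feature_matrix([w for w, _ in pairs])
    y = [m for _, m in pairs]
    return X, y


def run_stream(stream: ImuStream, bank: ClassifierBank,
               cal: CalibrationParams | None = None,
               filter_cfg: FilterConfig | None = None,
               smoother_cfg: SmootherConfig | None = None,
               streaming: bool = True) -> list[MotionEvent]:
    """Replay a raw stream through the full chain and emit one
    (timestamp, label, score, latency) event per detected step.

    ``streaming=True`` uses the online sample-by-sample segmenter;
    ``streaming=False`` uses the offline path.  Both produce identical
    events on the same stream (equivalence is contractual and tested).
    """
    if cal is not None:
        stream = compensate_stream(stream, cal)
    track = AttitudeFilter(filter_cfg).run(stream)
    user = project_stream(stream, track)
    cfg = smoother_cfg or SmootherConfig()
    if streaming:
        seg = StreamingSegmenter(cfg, rate_hz=stream.rate_hz)
        windows = []
        for i in range(len(user)):
            w = seg.push(user.t[i], user.gyro[i], user.accel[i],
                         attitude=track.rotation(i).as_matrix())
            if w is not None:
                windows.append(w)
    else:
        attitudes = np.array([track.rotation(i).as_matrix() for i in range(len(user))])
        windows = segment_stream(user, cfg, attitudes=attitudes)
    events = []
    for w in windows:
        X = feature_matrix([w])
        label, score = bank.predict_event(X[0])
        events.append(MotionEvent(t=w.peak_time, label=label, score=score,
                                  latency_samples=POST_SAMPLES + cfg.window_n))
    return events
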