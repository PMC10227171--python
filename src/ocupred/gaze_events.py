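"""Velocity estimation and velocity-threshold saccade detection.

The analysis chain mirrors standard oculomotor practice for video-based
trackers: the position signal is differentiated (central differences),
smoothed with a zero-phase 60 Hz low-pass filter, and saccades are the
maximal runs of samples whose 2-D speed exceeds a fixed 22 deg/s threshold.
Samples within 16 ms before a saccade onset and 70 ms after its offset are
excluded from pursuit statistics, and per-sample angular distances between
gaze and the circle / the fixation cross feed the trial-validity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .stimulus import StimulusTimeline
from .synthetic_gaze import GazeRecording

__all__ = [
    "VelocityTrace",
    "EventSet",
    "compute_velocity",
    "detect_saccades",
    "pursuit_mask",
    "distance_series",
    "analyze_recording",
    "VELOCITY_THRESHOLD",
    "PRE_MARGIN",
    "POST_MARGIN",
]

VELOCITY_THRESHOLD = 22.0  # deg/s
PRE_MARGIN = 0.016         # s excluded before saccade onset
POST_MARGIN = 0.070        # s excluded after saccade offset
FILTER_CUTOFF = 60.0       # Hz


@dataclass
class VelocityTrace:
    """Filtered eye-velocity signal for one recording."""

    timestamps: np.ndarray
    speed: np.ndarray       # deg/s, magnitude of 2-D velocity
    vx: np.ndarray          # deg/s, signed horizontal component
    vy: np.ndarray
    valid: np.ndarray       # per-sample validity mask

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class EventSet:
    """Detected saccades plus the masks and distances derived from them."""

    timestamps: np.ndarray
    saccades: list[tuple[float, float]]                 # (onset, offset) s
    pursuit_samples: np.ndarray                          # outside saccades+margins
    distance_to_circle: np.ndarray | None = None         # deg
    distance_to_cross: np.ndarray | None = None          # deg
    saccade_metrics: list[dict] = field(default_factory=list)


def compute_velocity(
    recording: GazeRecording,
    cutoff_hz: float = FILTER_CUTOFF,
    uniformity_rtol: float = 1e-6,
    edge_guard: float = 0.025,
) -> VelocityTrace:
    """Differentiate the gaze signal and smooth with a zero-phase low-pass.

    Central differences give the raw velocity; a second-order Butterworth
    filter applied forward and backward (``filtfilt``) realises the 60 Hz
    low-pass with unit DC gain and no phase lag, so event times are not
    biased in either direction.  Samples within ``edge_guard`` seconds of
    either end of the recording are flagged invalid: zero-phase filtering
    has start-up transients there, and one-sided differentiation makes the
    boundary estimates unreliable.
    """
    t = np.asarray(recording.timestamps, dtype=float)
    if t.size < 5:
        raise ValueError(f"need at least 5 samples, got {t.size}")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if np.any(np.abs(dt - dt0) > uniformity_rtol * dt0 + 1e-12):
        raise ValueError("timestamps are not uniformly sampled")
    fs = 1.0 / dt0

    vx = np.gradient(np.asarray(recording.gaze_x, dtype=float), dt0)
    vy = np.gradient(np.asarray(recording.gaze_y, dtype=float), dt0)
    if cutoff_hz < fs / 2.0:
        b, a = signal.butter(2, cutoff_hz / (fs / 2.0))
        vx = signal.filtfilt(b, a, vx)
        vy = signal.filtfilt(b, a, vy)
    speed = np.hypot(vx, vy)
    valid = (t - t[0] >= edge_guard) & (t[-1] - t >= edge_guard)
    return VelocityTrace(timestamps=t, speed=speed, vx=vx, vy=vy, valid=valid)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (inclusive) indices of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b - 1)) for a, b in zip(idx[::2], idx[1::2])]


def detect_saccades(
    trace: VelocityTrace,
    threshold: float = VELOCITY_THRESHOLD,
    min_duration: float = 0.010,
    merge_gap: float = 0.020,
) -> EventSet:
    """Fixed-velocity-threshold saccade detection.

    Maximal runs of samples with ``speed > threshold`` are candidate
    saccades; runs separated by less than ``merge_gap`` are merged (noise can
    momentarily dip the filtered speed below threshold mid-saccade), then
    runs shorter than ``min_duration`` are discarded.  Onset is the time of
    the first supra-threshold sample, offset the last.
    """
    t = trace.timestamps
    dt = 1.0 / trace.sample_rate
    runs = _runs((trace.speed > threshold) & trace.valid)

    merged: list[list[int]] = []
    for a, b in runs:
        if merged and t[a] - t[merged[-1][1]] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    kept = [(a, b) for a, b in merged if t[b] - t[a] + dt >= min_duration]

    saccades = [(float(t[a]), float(t[b])) for a, b in kept]
    metrics = []
    for a, b in kept:
        seg = slice(a, b + 1)
        metrics.append(
            {
                "onset": float(t[a]),
                "offset": float(t[b]),
                "peak_speed": float(trace.speed[seg].max()),
                "amplitude_deg": float(
                    np.abs(np.trapezoid(trace.vx[seg], t[seg]))
                ),
            }
        )
    events = EventSet(
        timestamps=t,
        saccades=saccades,
        pursuit_samples=np.ones(t.size, dtype=bool),
        saccade_metrics=metrics,
    )
    events.pursuit_samples = pursuit_mask(events)
    return events


def pursuit_mask(
    events: EventSet,
    pre_margin: float = PRE_MARGIN,
    post_margin: float = POST_MARGIN,
) -> np.ndarray:
    """Samples eligible for pursuit statistics.

    Excludes every sample within ``[onset - pre_margin, offset + post_margin]``
    of any detected saccade.
    """
    t = events.timestamps
    mask = np.ones(t.size, dtype=bool)
    for onset, offset in events.saccades:
        mask &= ~((t >= onset - pre_margin) & (t <= offset + post_margin))
    return mask


def distance_series(
    recording: GazeRecording, timeline: StimulusTimeline
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Euclidean angular distance to the circle and to the cross.

    The circle's position is defined throughout the trial, occlusion
    included (the notional motion continues); the cross sits at the origin.
    """
    t = np.asarray(recording.timestamps, dtype=float)
    tx = timeline.target_x(t)
    d_circle = np.hypot(recording.gaze_x - tx, recording.gaze_y)
    d_cross = np.hypot(recording.gaze_x - timeline.cross_position, recording.gaze_y)
    return d_circle, d_cross


def analyze_recording(
    recording: GazeRecording,
    timeline: StimulusTimeline,
    threshold: float = VELOCITY_THRESHOLD,
    cutoff_hz: float = FILTER_CUTOFF,
    pre_margin: float = PRE_MARGIN,
    post_margin: float = POST_MARGIN,
    min_duration: float = 0.010,
    merge_gap: float = 0.020,
) -> EventSet:
    """Full per-trial event analysis: velocity, saccades, masks, distances."""
    trace = compute_velocity(recording, cutoff_hz=cutoff_hz)
    events = detect_saccades(
        trace, threshold=threshold, min_duration=min_duration, merge_gap=merge_gap
    )
    events.pursuit_samples = pursuit_mask(events, pre_margin, post_margin)
    events.distance_to_circle, events.distance_to_cross = distance_series(
        recording, timeline
    )
    return events
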