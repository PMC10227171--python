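"""Seeded synthetic gaze and button-response generator.

Emulates an observer performing the pursuit / predictive-saccade paradigm in
front of a 200-ish Hz video-based eye tracker, with ground-truth labels for
every behaviour the downstream pipeline must recover:

* smooth pursuit of the moving circle with configurable gain, onset latency
  and band-limited position noise;
* in the saccade task (the predictive-saccade experiments), a saccade to the
  fixation cross initiated one detection latency after the speed
  perturbation, with main-sequence kinematics and a raised-cosine velocity
  profile, followed by fixation on the cross;
* in the pursuit task (the button-press control experiment), continued
  pursuit through occlusion plus a perturbation-response button press;
* a time-to-contact button press around the true TTC whose bias derives
  from a multiplicative error on the perceived post-change speed;
* occasional invalid trials produced by a slow gaze drift exceeding the
  3-degree validity rule, and occasional misses / false alarms.

Gaze noise is modelled as low-pass-filtered white noise: eye-position noise
in video trackers is temporally correlated, and unfiltered white noise at
200 Hz would alias into physiologically absurd velocity excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .stimulus import ExperimentDesign, StimulusTimeline, build_timeline

__all__ = [
    "OculomotorParams",
    "GazeRecording",
    "GroundTruth",
    "simulate_trial",
    "simulate_cohort",
    "CohortData",
    "saccade_velocity_profile",
]

SACCADE_TASK = "saccade_task"
PURSUIT_TASK = "pursuit_task"


@dataclass
class OculomotorParams:
    """Tunable parameters of the simulated observer and apparatus.

    Defaults are chosen to be physiologically plausible for this paradigm:
    pursuit gain a little below 1, perturbation-detection latency around
    300 ms, fixation noise within the tracker's stated 0.5-degree accuracy.
    """

    sample_rate: float = 200.0            # Hz (5 ms gaze-vector update)
    pursuit_gain: float = 0.95            # eye velocity / target velocity
    pursuit_onset_latency: float = 0.15   # s after motion onset
    detection_latency_mean: float = 0.3   # s, perturbation -> saccade/button
    detection_latency_sd: float = 0.05    # s
    saccade_miss_rate: float = 0.05       # P(no response to a perturbation)
    false_alarm_rate: float = 0.02        # P(response in a catch trial)
    main_sequence_slope: float = 30.0     # peak speed (deg/s) per deg amplitude
    fixation_noise_sd: float = 0.2        # deg, during fixation
    pursuit_noise_sd: float = 0.1         # deg, during pursuit
    noise_bandwidth_hz: float = 3.0       # low-pass cutoff of gaze noise
                                          # (fixational drift-like, few deg/s)
    landing_noise_sd: float = 0.4         # deg, saccade endpoint scatter
    ttc_bias_gain: float = 1.0            # perceived/actual post-change speed
    ttc_response_sd: float = 0.15         # s, TTC button-press jitter
    invalid_trial_rate: float = 0.0       # P(slow drift beyond 3 deg)

    def __post_init__(self) -> None:
        for name in ("saccade_miss_rate", "false_alarm_rate", "invalid_trial_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        for name in ("pursuit_onset_latency", "detection_latency_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ttc_bias_gain <= 0:
            raise ValueError(f"ttc_bias_gain must be positive, got {self.ttc_bias_gain}")

    def replace(self, **kw) -> "OculomotorParams":
        return replace(self, **kw)


@dataclass
class GazeRecording:
    """Uniformly sampled gaze trace for one trial plus button events."""

    trial_id: int
    timestamps: np.ndarray          # s, uniform at sample_rate
    gaze_x: np.ndarray              # deg, cross at 0
    gaze_y: np.ndarray              # deg
    button_events: list[tuple[float, str]] = field(default_factory=list)
    participant: str | int | None = None

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def button_times(self, kind: str) -> list[float]:
        return [t for t, k in self.button_events if k == kind]


@dataclass
class GroundTruth:
    """Generator-side labels used to validate the detection/scoring pipeline."""

    true_saccade_intervals: list[tuple[float, float]]
    perturbation_detected: bool
    true_detection_time: float | None
    true_ttc: float
    intended_validity: bool


def saccade_velocity_profile(amplitude: float, slope: float, t: np.ndarray) -> np.ndarray:
    """Raised-cosine saccade speed profile evaluated at times ``t`` from onset.

    Peak speed is ``slope * |amplitude|`` (the linear main-sequence regime)
    and the duration ``2 |A| / peak = 2 / slope`` follows from the profile
    integrating exactly to the amplitude.
    """
    peak = slope * abs(amplitude)
    dur = 2.0 * abs(amplitude) / peak  # == 2 / slope
    v = 0.5 * peak * (1.0 - np.cos(2.0 * np.pi * np.clip(t, 0.0, dur) / dur))
    v[(t < 0) | (t > dur)] = 0.0
    return np.sign(amplitude) * v


def _saccade_displacement(amplitude: float, slope: float, t: np.ndarray) -> np.ndarray:
    """Closed-form integral of the raised-cosine profile (deg from onset)."""
    peak = slope * abs(amplitude)
    dur = 2.0 * abs(amplitude) / peak
    tau = np.clip(t, 0.0, dur)
    disp = 0.5 * peak * (tau - dur * np.sin(2.0 * np.pi * tau / dur) / (2.0 * np.pi))
    return np.sign(amplitude) * disp


def _colored_noise(rng: np.random.Generator, n: int, sd: float, fs: float, cutoff: float) -> np.ndarray:
    """Band-limited Gaussian noise with stationary standard deviation ``sd``.

    Generated with padding on both ends so the low-pass start-up transient
    never reaches the returned segment (the noise process is stationary
    across the whole recording, edges included).
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    pad = max(50, int(4.0 * fs / max(cutoff, 1.0)))
    white = rng.standard_normal(n + 2 * pad)
    if cutoff < fs / 2 and n > 15:
        b, a = signal.butter(2, cutoff / (fs / 2.0))
        white = signal.filtfilt(b, a, white)
        seg = white[pad:-pad]
        s = seg.std()
        return sd * (seg / s if s > 0 else seg)
    return sd * white[pad:-pad]


def simulate_trial(
    timeline: StimulusTimeline,
    params: OculomotorParams,
    mode: str = SACCADE_TASK,
    seed: int | np.random.Generator = 0,
    trial_id: int = 0,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one trial of gaze and button behaviour.

    In ``saccade_task`` mode the observer pursues the circle and, if the
    perturbation is detected, saccades to the cross one detection latency
    after change onset, then fixates the cross.  In ``pursuit_task`` mode the
    observer keeps pursuing (the occluded target included) and signals
    detection with a ``perturbation_response`` button press.  Both modes end
    with a ``ttc_response`` press at
    ``change_onset + E_c / (v * ttc_bias_gain) + N(0, ttc_response_sd)``.

    Deterministic for a given integer seed.
    """
    if mode not in (SACCADE_TASK, PURSUIT_TASK):
        raise ValueError(f"mode must be '{SACCADE_TASK}' or '{PURSUIT_TASK}', got {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    fs = p.sample_rate
    dt = 1.0 / fs
    sacc_dur = 2.0 / p.main_sequence_slope
    if sacc_dur < 2.0 * dt:
        raise ValueError(
            f"sample_rate {fs} Hz too low to represent a saccade of duration "
            f"{sacc_dur * 1e3:.1f} ms (needs >= 2 samples)"
        )
    d = timeline.design

    # --- latent behavioural events (drawn before the trace so the sampling
    #     grid never perturbs the decision process) -------------------------
    perturbed = d.is_perturbed
    if perturbed:
        responds = rng.random() >= p.saccade_miss_rate
        latency = max(0.05, rng.normal(p.detection_latency_mean, p.detection_latency_sd))
        detection_time = timeline.change_onset + latency if responds else None
    else:
        responds = rng.random() < p.false_alarm_rate
        detection_time = timeline.change_onset + rng.uniform(0.2, 0.8) if responds else None

    perceived_speed = d.speed_condition * p.ttc_bias_gain
    press_time = (
        timeline.change_onset
        + d.change_onset_eccentricity / perceived_speed
        + rng.normal(0.0, p.ttc_response_sd)
    )
    press_time = max(press_time, timeline.change_onset + 0.1)

    make_drift = rng.random() < p.invalid_trial_rate

    t_end = max(timeline.ttc, press_time) + 0.3
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) * dt

    # --- base (noiseless) gaze -------------------------------------------
    x_target = timeline.target_x(t)
    pursuit_start = timeline.motion_onset + p.pursuit_onset_latency
    x0 = float(timeline.target_x(0.0))
    gaze = np.full(n, x0)
    on_pursuit = t >= pursuit_start
    # positional coupling with velocity gain: the eye covers `gain` times the
    # target's displacement since pursuit onset, i.e. a growing lag for gain<1
    x_ps = float(timeline.target_x(pursuit_start))
    gaze[on_pursuit] = x0 + p.pursuit_gain * (x_target[on_pursuit] - x_ps)

    saccade_intervals: list[tuple[float, float]] = []
    if mode == SACCADE_TASK and detection_time is not None:
        onset = detection_time
        i_on = int(np.searchsorted(t, onset))
        landing = timeline.cross_position + rng.normal(0.0, p.landing_noise_sd)
        amplitude = landing - gaze[min(i_on, n - 1)]
        if abs(amplitude) > 1e-9:
            during = t >= onset
            gaze[during] = gaze[min(i_on, n - 1)] + _saccade_displacement(
                amplitude, p.main_sequence_slope, t[during] - onset
            )
            saccade_intervals.append((onset, onset + sacc_dur))

    if make_drift:
        # slow linear drift during the pursuit phase, large enough to break
        # the 3-degree validity rule well before occlusion
        drift_start = timeline.motion_onset + 0.4
        drift_stop = saccade_intervals[0][0] if saccade_intervals else timeline.occlusion
        window = max(drift_stop - drift_start, 0.5)
        rate = 4.5 / window  # reaches 4.5 deg by drift_stop
        drift = rate * np.clip(t - drift_start, 0.0, drift_stop - drift_start)
        gaze = gaze + drift * (1 if rng.random() < 0.5 else -1)

    # --- noise ------------------------------------------------------------
    noise = _colored_noise(rng, n, 1.0, fs, p.noise_bandwidth_hz)
    sd = np.full(n, p.fixation_noise_sd)
    pursuing = on_pursuit.copy()
    if saccade_intervals:
        pursuing &= t < saccade_intervals[0][0]
    elif mode == PURSUIT_TASK:
        pursuing = on_pursuit
    sd[pursuing] = p.pursuit_noise_sd
    # ramp noise-amplitude transitions over ~100 ms: gaze noise levels change
    # gradually between fixation and pursuit, and a step in sd would inject a
    # spurious velocity transient at the boundary
    w = max(1, int(0.1 * fs))
    sd = np.convolve(sd, np.ones(w) / w, mode="same")
    gaze_x = gaze + sd * noise
    gaze_y = _colored_noise(rng, n, p.fixation_noise_sd * 0.5, fs, p.noise_bandwidth_hz)

    buttons: list[tuple[float, str]] = []
    if mode == PURSUIT_TASK and detection_time is not None:
        buttons.append((detection_time, "perturbation_response"))
    buttons.append((press_time, "ttc_response"))

    rec = GazeRecording(
        trial_id=trial_id, timestamps=t, gaze_x=gaze_x, gaze_y=gaze_y,
        button_events=buttons,
    )
    truth = GroundTruth(
        true_saccade_intervals=saccade_intervals,
        perturbation_detected=bool(perturbed and detection_time is not None),
        true_detection_time=detection_time,
        true_ttc=timeline.ttc,
        intended_validity=not make_drift,
    )
    return rec, truth


@dataclass
class CohortData:
    """All simulated recordings of a cohort, with ground truth and designs."""

    design: ExperimentDesign
    mode: str
    participants: list
    records: list  # (participant, trial_id, TrialDesign, GazeRecording, GroundTruth)

    def __len__(self) -> int:
        return len(self.records)

    def gaze_frame(self):
        import pandas as pd

        frames = []
        for pid, tid, _d, rec, _g in self.records:
            frames.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "trial_id": tid,
                        "t": rec.timestamps,
                        "x_deg": rec.gaze_x,
                        "y_deg": rec.gaze_y,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def events_frame(self):
        import pandas as pd

        rows = [
            {"participant": pid, "trial_id": tid, "time": time, "kind": kind}
            for pid, tid, _d, rec, _g in self.records
            for time, kind in rec.button_events
        ]
        return pd.DataFrame(rows)

    def truth_frame(self):
        import pandas as pd

        rows = []
        for pid, tid, _d, _rec, g in self.records:
            on, off = (g.true_saccade_intervals[0] if g.true_saccade_intervals else (None, None))
            rows.append(
                {
                    "participant": pid,
                    "trial_id": tid,
                    "saccade_onset": on,
                    "saccade_offset": off,
                    "perturbation_detected": g.perturbation_detected,
                    "true_detection_time": g.true_detection_time,
                    "true_ttc": g.true_ttc,
                    "intended_validity": g.intended_validity,
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(
    design: ExperimentDesign,
    per_participant_params: list[OculomotorParams] | dict,
    seed: int = 0,
    mode: str = SACCADE_TASK,
) -> CohortData:
    """Simulate every trial of ``design`` for each participant.

    ``per_participant_params`` maps participant ids to their
    :class:`OculomotorParams`: a dict, a list of ``(id, params)`` pairs, or
    a plain list of params (keyed ``P00, P01, ...``).  Each (participant,
    trial) gets an independent child seed spawned from ``seed``, so the
    whole cohort is reproducible bit-for-bit.
    """
    if isinstance(per_participant_params, dict):
        items = list(per_participant_params.items())
    elif per_participant_params and isinstance(per_participant_params[0], tuple):
        items = list(per_participant_params)
    else:
        items = [(f"P{i:02d}", p) for i, p in enumerate(per_participant_params)]
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate participant ids: {ids}")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(items))
    records = []
    for (pid, params), child in zip(items, child_seeds):
        trial_seeds = child.spawn(len(design.trials))
        for tid, (tdesign, tseed) in enumerate(zip(design.trials, trial_seeds)):
            timeline = build_timeline(tdesign)
            rec, truth = simulate_trial(
                timeline, params, mode=mode,
                seed=np.random.default_rng(tseed), trial_id=tid,
            )
            rec.participant = pid
            records.append((pid, tid, tdesign, rec, truth))
    return CohortData(design=design, mode=mode, participants=ids, records=records)
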