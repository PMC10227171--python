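"""Diagnostic plots: stimulus space-time diagram and eye-velocity profiles."""

from __future__ import annotations

import numpy as np

from .gaze_events import compute_velocity
from .stimulus import StimulusTimeline
from .synthetic_gaze import CohortData

__all__ = ["plot_timeline", "plot_mean_eye_velocity"]


def plot_timeline(timeline: StimulusTimeline, ax=None):
    """Space-time plot of one trial: target position, occlusion, events."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    t = np.linspace(0.0, timeline.ttc + 0.5, 400)
    pos = timeline.target_position(t)
    vis = timeline.visibility(t)
    ax.plot(t[vis], pos[vis], color="k", label="target (visible)")
    ax.plot(t[~vis], pos[~vis], color="k", ls="--", label="target (occluded)")
    for name in ("motion_onset", "change_onset", "occlusion", "ttc"):
        ax.axvline(getattr(timeline, name), color="grey", lw=0.5)
        ax.text(getattr(timeline, name), ax.get_ylim()[1], name,
                rotation=90, va="top", fontsize=7)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("eccentricity from cross (deg)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_mean_eye_velocity(cohort: CohortData, align_to: str = "change_onset",
                           window: tuple[float, float] = (-0.5, 1.5), ax=None):
    """Trial-averaged eye speed around the perturbation, per speed condition.

    Reproduces the qualitative profile of the paradigm: pursuit at the
    pre-change speed, the post-change pursuit step, and (in the saccade
    task) the saccadic spike followed by near-zero fixation velocity.
    """
    import matplotlib.pyplot as plt

    from .stimulus import build_timeline

    if ax is None:
        _fig, ax = plt.subplots()
    by_speed: dict[float, list[np.ndarray]] = {}
    grid = None
    for _pid, _tid, d, rec, _g in cohort.records:
        tl = build_timeline(d)
        trace = compute_velocity(rec)
        rel = trace.timestamps - getattr(tl, align_to)
        if grid is None:
            grid = np.arange(window[0], window[1], 1.0 / trace.sample_rate)
        by_speed.setdefault(d.speed_condition, []).append(
            np.interp(grid, rel, trace.speed)
        )
    for v in sorted(by_speed):
        ax.plot(grid, np.mean(by_speed[v], axis=0), label=f"{v:g} deg/s")
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(f"time from {align_to} (s)")
    ax.set_ylabel("eye speed (deg/s)")
    ax.legend(fontsize=8)
    return ax
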