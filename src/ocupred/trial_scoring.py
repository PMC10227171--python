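"""Trial-level scoring: validity, correctness, response times, TTC error.

A trial is *valid* when gaze stayed within 3 degrees of the instructed
locus: the circle during the (visible-target) pursuit phase and, after a
saccade to the cross, the cross during the fixation phase.  A *correct*
trial pairs a perturbation with a qualifying response (a saccade landing on
the cross in the predictive-saccade task, a button press in the pursuit
control task) and a catch trial with the absence of one.  Response time is
measured from perturbation onset; the time-to-contact (TTC) prediction
error is the signed difference between the TTC button press and the true
contact time, also expressed relative to the change-onset-to-TTC interval
(0% = press at change onset, 100% = press exactly at contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaze_events import EventSet, analyze_recording
from .stimulus import StimulusTimeline, build_timeline
from .synthetic_gaze import SACCADE_TASK, PURSUIT_TASK, CohortData, GazeRecording

__all__ = [
    "TrialScore",
    "ScoreTable",
    "classify_validity",
    "classify_correct",
    "response_time",
    "ttc_error",
    "score_trial",
    "score_cohort",
    "aggregate",
    "DISTANCE_THRESHOLD",
    "MIN_VALID_TRIALS",
]

DISTANCE_THRESHOLD = 3.0  # deg, gaze-to-locus validity rule
MIN_VALID_TRIALS = 10     # per cell; fewer excludes the participant


@dataclass
class TrialScore:
    trial_id: int
    participant: str | int | None
    speed: float
    occlusion_delay: float
    valid: bool
    correct: bool | None
    saccadic_rt: float | None = None      # s, saccade tasks
    perturbation_rt: float | None = None  # s, pursuit/button task
    ttc_error: float | None = None        # s, signed (predicted - actual)
    relative_ttc: float | None = None     # % of change-onset -> TTC interval


@dataclass
class ScoreTable:
    """Participant x speed x occlusion aggregates, after exclusions."""

    table: pd.DataFrame
    excluded_participants: list = field(default_factory=list)

    def measure_frame(self, measure: str) -> pd.DataFrame:
        """Long-format participant x condition frame for one measure."""
        cols = ["participant", "speed", "occlusion_delay", measure]
        return self.table.reset_index()[cols].dropna(subset=[measure])


def _qualifying_saccades(
    recording: GazeRecording,
    events: EventSet,
    timeline: StimulusTimeline,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> list[tuple[float, float]]:
    """Saccades whose endpoint lies within the threshold of the cross."""
    t = np.asarray(recording.timestamps)
    out = []
    for onset, offset in events.saccades:
        i = min(int(np.searchsorted(t, offset)), t.size - 1)
        d = float(
            np.hypot(
                recording.gaze_x[i] - timeline.cross_position, recording.gaze_y[i]
            )
        )
        if d <= distance_threshold:
            out.append((onset, offset))
    return out


def classify_validity(
    recording: GazeRecording,
    events: EventSet,
    timeline: StimulusTimeline,
    mode: str = SACCADE_TASK,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> bool:
    """Gaze-based trial validity (strict ``> threshold`` comparison).

    Pursuit phase runs from motion onset to the first qualifying saccade
    onset or, without one, to occlusion; gaze must stay within the threshold
    of the circle (saccade samples and their margins are not held against
    pursuit).  In the saccade task the fixation phase runs from saccade
    offset to the TTC press (or trial end) and is checked against the cross.
    """
    if events.distance_to_circle is None:
        raise ValueError("events must carry distance series (use analyze_recording)")
    t = np.asarray(recording.timestamps)
    quals = (
        _qualifying_saccades(recording, events, timeline, distance_threshold)
        if mode == SACCADE_TASK
        else []
    )
    pursuit_end = min(quals[0][0], timeline.occlusion) if quals else timeline.occlusion

    in_pursuit = (t >= timeline.motion_onset) & (t < pursuit_end) & events.pursuit_samples
    if np.any(events.distance_to_circle[in_pursuit] > distance_threshold):
        return False

    if quals:
        press = recording.button_times("ttc_response")
        fix_end = min(press) if press else t[-1]
        in_fix = (t >= quals[0][1]) & (t <= fix_end) & events.pursuit_samples
        if np.any(events.distance_to_cross[in_fix] > distance_threshold):
            return False
    return True


def classify_correct(
    recording: GazeRecording,
    events: EventSet,
    timeline: StimulusTimeline,
    mode: str = SACCADE_TASK,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> bool:
    """Perceptual-judgement correctness.

    Saccade task: a perturbation trial is correct when a qualifying saccade
    to the cross was initiated after change onset; a catch trial is correct
    when no cross-directed saccade occurred at all.  Anticipatory
    cross-directed saccades (onset before change onset) make any trial
    incorrect.  Pursuit task: the button press substitutes for the saccade.
    """
    perturbed = timeline.design.is_perturbed
    if mode == SACCADE_TASK:
        quals = _qualifying_saccades(recording, events, timeline, distance_threshold)
        if any(onset <= timeline.change_onset for onset, _ in quals):
            return False
        responded = any(onset > timeline.change_onset for onset, _ in quals)
    else:
        presses = recording.button_times("perturbation_response")
        if any(p <= timeline.change_onset for p in presses):
            return False
        responded = any(p > timeline.change_onset for p in presses)
    return responded if perturbed else not responded


def response_time(
    recording: GazeRecording,
    events: EventSet,
    timeline: StimulusTimeline,
    mode: str = SACCADE_TASK,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> float | None:
    """Time from change onset to the first qualifying response, seconds.

    Defined only for correct perturbation trials; ``None`` otherwise.
    """
    if not timeline.design.is_perturbed:
        return None
    if not classify_correct(recording, events, timeline, mode, distance_threshold):
        return None
    if mode == SACCADE_TASK:
        quals = _qualifying_saccades(recording, events, timeline, distance_threshold)
        onsets = [on for on, _ in quals if on > timeline.change_onset]
    else:
        onsets = [
            p
            for p in recording.button_times("perturbation_response")
            if p > timeline.change_onset
        ]
    return min(onsets) - timeline.change_onset if onsets else None


def ttc_error(
    recording: GazeRecording, timeline: StimulusTimeline
) -> tuple[float | None, float | None]:
    """Signed TTC prediction error (s) and relative prediction timing (%).

    ``error = press - ttc``;
    ``relative = 100 * (press - change_onset) / (ttc - change_onset)``.
    """
    presses = recording.button_times("ttc_response")
    if not presses:
        return None, None
    press = min(presses)
    err = press - timeline.ttc
    rel = 100.0 * (press - timeline.change_onset) / (timeline.ttc - timeline.change_onset)
    return err, rel


def score_trial(
    recording: GazeRecording,
    timeline: StimulusTimeline,
    events: EventSet | None = None,
    mode: str = SACCADE_TASK,
    distance_threshold: float = DISTANCE_THRESHOLD,
    **detect_kwargs,
) -> TrialScore:
    """Score one trial end to end (detection included unless ``events`` given)."""
    if events is None:
        events = analyze_recording(recording, timeline, **detect_kwargs)
    valid = classify_validity(recording, events, timeline, mode, distance_threshold)
    correct = classify_correct(recording, events, timeline, mode, distance_threshold)
    rt = response_time(recording, events, timeline, mode, distance_threshold)
    err = rel = None
    if correct:
        err, rel = ttc_error(recording, timeline)
    d = timeline.design
    return TrialScore(
        trial_id=recording.trial_id,
        participant=recording.participant,
        speed=d.speed_condition,
        occlusion_delay=d.occlusion_delay,
        valid=valid,
        correct=correct,
        saccadic_rt=rt if mode == SACCADE_TASK else None,
        perturbation_rt=rt if mode == PURSUIT_TASK else None,
        ttc_error=err,
        relative_ttc=rel,
    )


def score_cohort(cohort: CohortData, **kwargs) -> list[TrialScore]:
    """Score every simulated trial of a cohort."""
    scores = []
    for pid, tid, tdesign, rec, _truth in cohort.records:
        timeline = build_timeline(tdesign)
        scores.append(score_trial(rec, timeline, mode=cohort.mode, **kwargs))
    return scores


def scores_frame(scores: list[TrialScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def aggregate(
    scores: list[TrialScore] | pd.DataFrame,
    min_valid_trials: int = MIN_VALID_TRIALS,
) -> ScoreTable:
    """Participant x condition summary with the low-valid-count exclusion.

    Percentage correct is ``100 * n_correct / n_valid`` per cell; response
    times and TTC errors are summarised (mean and median) over valid correct
    trials.  A participant with fewer than ``min_valid_trials`` valid trials
    in any cell is excluded from the returned table.
    """
    df = scores_frame(scores) if not isinstance(scores, pd.DataFrame) else scores.copy()
    if df.empty:
        raise ValueError("no trial scores to aggregate")

    rt_col = df["saccadic_rt"].where(df["saccadic_rt"].notna(), df["perturbation_rt"])
    df = df.assign(_rt=rt_col)
    valid = df[df["valid"]]

    def _mean(s: pd.Series) -> float:
        s = s.dropna()
        return float(s.mean()) if len(s) else np.nan

    def _median(s: pd.Series) -> float:
        s = s.dropna()
        return float(s.median()) if len(s) else np.nan

    def _cell(g: pd.DataFrame) -> pd.Series:
        n_valid = len(g)
        n_correct = int(g["correct"].sum())
        ok = g[g["correct"].astype(bool)]
        return pd.Series(
            {
                "n_valid": n_valid,
                "n_correct": n_correct,
                "percent_correct": 100.0 * n_correct / n_valid if n_valid else np.nan,
                "mean_rt": _mean(ok["_rt"]),
                "median_rt": _median(ok["_rt"]),
                "mean_ttc_error": _mean(ok["ttc_error"]),
                "median_ttc_error": _median(ok["ttc_error"]),
                "mean_relative_ttc": _mean(ok["relative_ttc"]),
            }
        )

    keys = ["participant", "speed", "occlusion_delay"]
    # count valid trials on the full factorial grid so empty cells exclude too
    grid = (
        df.groupby(keys, dropna=False)["valid"].sum().rename("n_valid_all").reset_index()
    )
    excluded = sorted(
        grid.loc[grid["n_valid_all"] < min_valid_trials, "participant"].unique().tolist()
    )
    cells = valid.groupby(keys, dropna=False).apply(_cell, include_groups=False)
    table = cells[~cells.index.get_level_values("participant").isin(excluded)]
    return ScoreTable(table=table, excluded_participants=excluded)
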