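"""Kinematic stimulus model for the pursuit/predictive-saccade paradigm.

A white circle appears at 14 degrees of eccentricity from a fixation cross,
starts moving toward the cross at 4 deg/s after 1 s, and 1 s later either
slows to 3 deg/s, speeds up to 5 deg/s, or keeps moving at 4 deg/s (the
speed perturbation).  Some time after the perturbation the circle is
occluded but notionally keeps moving; the observer predicts the moment the
circle's centre coincides with the cross (time to contact, TTC).

Everything in this module is analytic: positions are piecewise-linear
functions of time on a one-dimensional signed axis with the cross at the
origin and positive values toward the side where the circle started.
Screen millimetres are a derived view via the exact tangent conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesign",
    "StimulusTimeline",
    "ExperimentDesign",
    "build_timeline",
    "eccentricity_at_occlusion",
    "time_to_ttc_from_occlusion",
    "peripheral_monitoring_time",
    "generate_design",
    "degrees_to_screen_mm",
    "screen_mm_to_degrees",
    "stimulus_table",
    "SPEED_CONDITIONS",
    "OCCLUSION_DELAYS_EXP1",
    "OCCLUSION_DELAYS_EXP23",
]

#: Post-perturbation target speeds (deg/s).  4 deg/s is the no-change catch
#: condition (same speed as the pre-perturbation phase).
SPEED_CONDITIONS = (3.0, 4.0, 5.0)

OCCLUSION_DELAYS_EXP1 = (1.0, 1.5)
OCCLUSION_DELAYS_EXP23 = (0.3, 0.5, 0.7, 0.9)


@dataclass
class TrialDesign:
    """Factors and geometry of a single trial.

    Parameters
    ----------
    speed_condition : float
        Target angular speed after the perturbation, deg/s.
    occlusion_delay : float
        Seconds between perturbation onset and target occlusion.
    side : str
        Side of the cross where the circle starts, ``"left"`` or ``"right"``.
    pre_motion_duration : float
        Stationary period after stimulus appearance, s.
    pre_change_speed : float
        Target speed before the perturbation, deg/s.
    pre_change_duration : float
        Duration of the pre-perturbation motion phase, s.
    initial_eccentricity : float
        Circle-to-cross angular distance at appearance, deg.
    """

    speed_condition: float
    occlusion_delay: float
    side: str = "right"
    pre_motion_duration: float = 1.0
    pre_change_speed: float = 4.0
    pre_change_duration: float = 1.0
    initial_eccentricity: float = 14.0

    def __post_init__(self) -> None:
        if self.speed_condition <= 0:
            raise ValueError(
                f"speed_condition must be positive, got {self.speed_condition}"
            )
        if self.occlusion_delay <= 0:
            raise ValueError(
                f"occlusion_delay must be positive, got {self.occlusion_delay}"
            )
        if self.pre_change_speed <= 0:
            raise ValueError(
                f"pre_change_speed must be positive, got {self.pre_change_speed}"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def is_perturbed(self) -> bool:
        """True when the trial contains a speed change."""
        return self.speed_condition != self.pre_change_speed

    @property
    def change_onset_eccentricity(self) -> float:
        """Eccentricity at the moment of the speed change (10 deg under defaults)."""
        return self.initial_eccentricity - self.pre_change_speed * self.pre_change_duration


@dataclass
class StimulusTimeline:
    """Event times and analytic target trajectory for one trial.

    All times are on the trial clock (stimulus appearance at t = 0).  The
    target position is signed eccentricity relative to the cross: positive
    while the circle has not yet arrived, zero exactly at TTC, negative if
    the notional motion overshoots.
    """

    design: TrialDesign
    motion_onset: float
    change_onset: float
    occlusion: float
    ttc: float
    appearance: float = 0.0

    def target_position(self, t):
        """Signed circle-to-cross eccentricity (deg) at time ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        d = self.design
        pre = d.initial_eccentricity - d.pre_change_speed * np.clip(
            t - self.motion_onset, 0.0, d.pre_change_duration
        )
        post = d.change_onset_eccentricity - d.speed_condition * (t - self.change_onset)
        pos = np.where(t < self.change_onset, pre, post)
        return pos if pos.ndim else float(pos)

    def target_x(self, t):
        """Horizontal screen coordinate of the circle, deg; cross at 0."""
        sign = 1.0 if self.design.side == "right" else -1.0
        return sign * self.target_position(t)

    def visibility(self, t):
        """True while the circle is displayed (before occlusion)."""
        t = np.asarray(t, dtype=float)
        vis = t < self.occlusion
        return vis if vis.ndim else bool(vis)

    @property
    def cross_position(self) -> float:
        return 0.0


def build_timeline(design: TrialDesign) -> StimulusTimeline:
    """Derive the trial's event times from its design.

    Events satisfy ``motion_onset = pre_motion_duration``,
    ``change_onset = motion_onset + pre_change_duration``,
    ``occlusion = change_onset + occlusion_delay`` and
    ``ttc = change_onset + E_c / v`` where ``E_c`` is the eccentricity at
    change onset and ``v`` the post-change speed.
    """
    motion_onset = design.pre_motion_duration
    change_onset = motion_onset + design.pre_change_duration
    occlusion = change_onset + design.occlusion_delay
    ttc = change_onset + design.change_onset_eccentricity / design.speed_condition
    return StimulusTimeline(
        design=design,
        motion_onset=motion_onset,
        change_onset=change_onset,
        occlusion=occlusion,
        ttc=ttc,
    )


def eccentricity_at_occlusion(design: TrialDesign) -> float:
    """Circle-to-cross distance (deg) at the moment of occlusion.

    Raises
    ------
    ValueError
        If the circle would reach (or pass) the cross before occlusion,
        i.e. the geometry is invalid.
    """
    ecc = design.change_onset_eccentricity - design.speed_condition * design.occlusion_delay
    if ecc <= 0:
        raise ValueError(
            "invalid geometry: target reaches the cross before occlusion "
            f"(speed_condition={design.speed_condition}, "
            f"occlusion_delay={design.occlusion_delay})"
        )
    return ecc


def time_to_ttc_from_occlusion(design: TrialDesign) -> float:
    """Seconds between target occlusion and the true time to contact."""
    return eccentricity_at_occlusion(design) / design.speed_condition


def peripheral_monitoring_time(design: TrialDesign, assumed_latency: float = 0.3) -> float:
    """Time the (visible) target can be monitored peripherally after the saccade.

    Assumes the saccade to the cross is initiated ``assumed_latency`` seconds
    after the perturbation; floored at zero when the target is occluded
    before the saccade lands.
    """
    if assumed_latency < 0:
        raise ValueError(f"assumed_latency must be non-negative, got {assumed_latency}")
    return max(0.0, design.occlusion_delay - assumed_latency)


@dataclass
class ExperimentDesign:
    """A full experiment: ordered trials plus the factorial cell counts."""

    experiment_id: int
    trials: list[TrialDesign] = field(default_factory=list)
    trials_per_cell: dict[tuple[float, float], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def max_speed_run_length(self) -> int:
        """Longest run of consecutive trials with the same speed condition."""
        best = run = 0
        prev = None
        for t in self.trials:
            run = run + 1 if t.speed_condition == prev else 1
            prev = t.speed_condition
            best = max(best, run)
        return best

    def to_frame(self) -> pd.DataFrame:
        """One row per trial: id, factors, and derived event times."""
        rows = []
        for i, d in enumerate(self.trials):
            tl = build_timeline(d)
            rows.append(
                {
                    "trial_id": i,
                    "speed": d.speed_condition,
                    "occlusion_delay": d.occlusion_delay,
                    "side": d.side,
                    "motion_onset": tl.motion_onset,
                    "change_onset": tl.change_onset,
                    "occlusion": tl.occlusion,
                    "ttc": tl.ttc,
                }
            )
        return pd.DataFrame(rows)


def _cell_counts(experiment_id: int) -> dict[tuple[float, float], int]:
    if experiment_id == 1:
        return {
            (v, occ): 40 for v in SPEED_CONDITIONS for occ in OCCLUSION_DELAYS_EXP1
        }
    if experiment_id in (2, 3):
        counts = {}
        for occ in OCCLUSION_DELAYS_EXP23:
            counts[(3.0, occ)] = 30
            counts[(5.0, occ)] = 30
            counts[(4.0, occ)] = 10
        return counts
    raise ValueError(f"experiment_id must be 1, 2 or 3, got {experiment_id}")


def generate_design(
    experiment_id: int,
    seed: int,
    cell_counts: dict[tuple[float, float], int] | None = None,
    max_run: int = 3,
    max_restarts: int = 200,
) -> ExperimentDesign:
    """Generate a quasi-randomized trial order for one experiment.

    The order is a seeded random permutation of the declared factorial cells
    subject to the constraint that the same speed condition never occurs more
    than ``max_run`` times in a row.  The sequence is built greedily: each
    next trial is drawn among the speeds that do not violate the run-length
    constraint, weighted by how many trials of that speed remain (which keeps
    dead ends rare); the construction restarts on a dead end.

    Deterministic for a given seed.  ``cell_counts`` overrides the printed
    design with a custom ``{(speed, occlusion): n}`` mapping.
    """
    counts = dict(cell_counts) if cell_counts is not None else _cell_counts(experiment_id)
    rng = np.random.default_rng(seed)
    speeds = sorted({v for v, _ in counts})

    for _ in range(max_restarts):
        remaining = {
            v: [occ for (vv, occ), n in sorted(counts.items()) if vv == v for _ in range(n)]
            for v in speeds
        }
        for v in speeds:
            rng.shuffle(remaining[v])
        order: list[tuple[float, float]] = []
        run_speed, run_len = None, 0
        dead = False
        while any(remaining[v] for v in speeds):
            eligible = [
                v
                for v in speeds
                if remaining[v] and not (v == run_speed and run_len >= max_run)
            ]
            if not eligible:
                dead = True
                break
            weights = np.array([len(remaining[v]) for v in eligible], dtype=float)
            v = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
            order.append((v, remaining[v].pop()))
            run_len = run_len + 1 if v == run_speed else 1
            run_speed = v
        if not dead:
            trials = [
                TrialDesign(
                    speed_condition=v,
                    occlusion_delay=occ,
                    side="right" if rng.random() < 0.5 else "left",
                )
                for v, occ in order
            ]
            return ExperimentDesign(
                experiment_id=experiment_id, trials=trials, trials_per_cell=counts
            )
    raise RuntimeError(
        f"could not satisfy run-length <= {max_run} after {max_restarts} restarts"
    )


def degrees_to_screen_mm(angle_deg: float, viewing_distance_m: float = 1.2) -> float:
    """Exact tangent conversion from visual angle to screen millimetres."""
    angle_deg = np.asarray(angle_deg, dtype=float)
    if np.any(np.abs(angle_deg) >= 90):
        raise ValueError("angle must satisfy |angle| < 90 degrees")
    mm = 1000.0 * viewing_distance_m * np.tan(np.deg2rad(angle_deg))
    return mm if mm.ndim else float(mm)


def screen_mm_to_degrees(mm: float, viewing_distance_m: float = 1.2) -> float:
    """Inverse of :func:`degrees_to_screen_mm`."""
    mm = np.asarray(mm, dtype=float)
    deg = np.rad2deg(np.arctan2(mm, 1000.0 * viewing_distance_m))
    return deg if deg.ndim else float(deg)


def stimulus_table() -> pd.DataFrame:
    """Analytic table of the paradigm's 18 speed-by-occlusion conditions.

    For every combination of post-change speed {3, 4, 5} deg/s and occlusion
    delay {0.3, 0.5, 0.7, 0.9, 1.0, 1.5} s (under default geometry) returns
    the eccentricity at occlusion, the remaining time to contact and the
    approximate peripheral monitoring time, rounded as conventionally
    reported (1, 2 and 1 decimals respectively).
    """
    rows = []
    for v in SPEED_CONDITIONS:
        for occ in sorted(set(OCCLUSION_DELAYS_EXP23 + OCCLUSION_DELAYS_EXP1)):
            d = TrialDesign(speed_condition=v, occlusion_delay=occ)
            rows.append(
                {
                    "speed": v,
                    "occlusion_ms": round(occ * 1000),
                    "eccentricity_at_occlusion_deg": round(eccentricity_at_occlusion(d), 1),
                    "time_to_ttc_s": round(time_to_ttc_from_occlusion(d), 2),
                    "peripheral_monitoring_s": round(peripheral_monitoring_time(d), 1),
                }
            )
    return pd.DataFrame(rows)


def _conservation_residual(design: TrialDesign) -> float:
    """Distance bookkeeping: time-to-TTC * v + v * t_occ must equal E_c."""
    v = design.speed_condition
    return (
        time_to_ttc_from_occlusion(design) * v
        + v * design.occlusion_delay
        - design.change_onset_eccentricity
    )
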