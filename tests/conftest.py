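import numpy as np
import pytest

from ocupred import OculomotorParams, TrialDesign, build_timeline, generate_design, simulate_cohort


@pytest.fixture
def noiseless_params() -> OculomotorParams:
    """Deterministic observer: unit gain, zero latencies and noise."""
    return OculomotorParams(
        pursuit_gain=1.0,
        pursuit_onset_latency=0.0,
        detection_latency_sd=0.0,
        saccade_miss_rate=0.0,
        false_alarm_rate=0.0,
        fixation_noise_sd=0.0,
        pursuit_noise_sd=0.0,
        landing_noise_sd=0.0,
        ttc_response_sd=0.0,
        invalid_trial_rate=0.0,
    )


@pytest.fixture
def default_params() -> OculomotorParams:
    return OculomotorParams()


@pytest.fixture
def perturbed_timeline():
    """3 deg/s perturbation, 1 s occlusion (a standard long-occlusion trial)."""
    return build_timeline(TrialDesign(speed_condition=3.0, occlusion_delay=1.0))


@pytest.fixture
def catch_timeline():
    """4 deg/s no-change catch trial."""
    return build_timeline(TrialDesign(speed_condition=4.0, occlusion_delay=1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x a reduced 60-trial design, saccade task, defaults."""
    design = generate_design(1, seed=11, cell_counts={
        (v, occ): 10 for v in (3.0, 4.0, 5.0) for occ in (1.0, 1.5)
    })
    params = [OculomotorParams() for _ in range(3)]
    return simulate_cohort(design, params, seed=42, mode="saccade_task")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
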