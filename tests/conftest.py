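import numpy as np
import pytest
from hypothesis import settings

from emsopt.config import ScenarioConfig, ServiceDist

# Property tests must behave identically on every run.
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """A light 2-day scenario for fast end-to-end simulator tests."""
    return ScenarioConfig(horizon_days=2, warmup_days=0, seed=7)


def single_class_config(
    arrivals_per_day: float,
    exam_mean_min: float,
    physicians: int,
    horizon_days: int = 40,
    seed: int = 0,
) -> ScenarioConfig:
    """A reduced configuration that collapses the model to one M/M/c station.

    Registration is instantaneous, no checkups, no admissions, no
    diversion and no competing outpatient load, so the only queue is the
    physician station with exponential service.
    """
    dists = {
        "registration": ServiceDist("deterministic", {"value": 0.0}),
        "exam": ServiceDist("exponential", {"mean": exam_mean_min}),
        "urine": ServiceDist("deterministic", {"value": 0.0}),
        "ct": ServiceDist("deterministic", {"value": 0.0}),
        "xray": ServiceDist("deterministic", {"value": 0.0}),
    }
    return ScenarioConfig(
        signal_M=physicians,
        noise_lambda=arrivals_per_day,
        triage_mix=(0.0, 0.0, 1.0, 0.0, 0.0),
        service_dists=dists,
        checkup_probs={"urine": 0.0, "ct": 0.0, "xray": 0.0},
        admit_probs=(0.0, 0.0, 0.0, 0.0, 0.0),
        outpatient_rate_per_day=0.0,
        p_divert=0.0,
        horizon_days=horizon_days,
        warmup_days=2,
        seed=seed,
        registration_servers=1,
        beds_Bt=500,
    )
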