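import numpy as np
import pytest
from hypothesis import settings

from exenergy import BreathSeries, ExpFitParams, SynthSpec

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture
def mono_truth() -> ExpFitParams:
    return ExpFitParams(model="mono", baseline=300.0, A1=1000.0, tau1=48.0, td=5.0)


@pytest.fixture
def bi_truth() -> ExpFitParams:
    return ExpFitParams(
        model="bi", baseline=300.0, A1=1200.0, tau1=30.0, td=0.0,
        A2=400.0, tau2=300.0,
    )


@pytest.fixture
def clean_mono_series(mono_truth) -> BreathSeries:
    """Noise-free mono-exponential recovery sampled every second for 10 min."""
    t = np.arange(0.0, 601.0)
    vo2 = mono_truth.baseline + mono_truth.A1 * np.exp(
        -np.maximum(t - mono_truth.td, 0.0) / mono_truth.tau1
    )
    return BreathSeries(times=t, vo2=vo2, phase="recovery")


@pytest.fixture
def clean_spec(mono_truth) -> SynthSpec:
    return SynthSpec(
        recovery=mono_truth, noise_sd=0.0, jitter=0.0, mean_interval=1.0, seed=7
    )
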