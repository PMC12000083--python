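import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reframe_gait import ReframeConfig, RunManifest, SyntheticConfig, build_study, run_pipeline

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: 2 subjects x 2 knees x 3 trials, 5 marker sets,
    constant misalignments only (STA off)."""
    return SyntheticConfig(n_subjects=2, trials_per_knee=3, rate_hz=100.0,
                           cycle_duration_s=1.0, seed=7).without_sta()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return build_study(small_config)


@pytest.fixture(scope="session")
def small_run(small_config):
    """One full pipeline execution on the scaled study, shared across tests."""
    manifest = RunManifest(reframe=ReframeConfig(), synthetic=small_config,
                           seed=small_config.seed, make_plots=False)
    return run_pipeline(manifest)
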