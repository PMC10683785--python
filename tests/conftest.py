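import numpy as np
import pytest

from pepkit.pipeline import RunConfig
from pepkit.protocol import build_default_protocol
from pepkit.simulate import GeneratorConfig, build_cohort_profiles, simulate_subject_recording


@pytest.fixture(scope="session")
def protocol():
    return build_default_protocol()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def subject_recording(protocol, default_config):
    """One default-protocol subject session (young male, seed-fixed)."""
    profile = build_cohort_profiles(default_config)[0]
    rng = np.random.default_rng(1234)
    return simulate_subject_recording(profile, protocol, default_config, rng)


@pytest.fixture(scope="session")
def small_run_config():
    """8-subject cohort config for fast end-to-end runs."""
    gen = GeneratorConfig(n_per_cell=2, dropout_events=4, seed=5)
    return RunConfig(generator=gen, make_figures=False)


@pytest.fixture(scope="session")
def small_run_result(small_run_config):
    from pepkit.pipeline import run_pipeline

    return run_pipeline(small_run_config)
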