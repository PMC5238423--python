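import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-configuration pipeline run shared across tests."""
    from migraphen.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    results = run_pipeline(PipelineConfig(), out)
    return results, out


@pytest.fixture(scope="session")
def small_config():
    """Reduced population for fast pipeline smoke tests."""
    from migraphen.synthetic import SimulationConfig

    return SimulationConfig(n_residents=3, n_migrants=6, years=(2002, 2005),
                            fix_interval_hours=2.0, seed=7)
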