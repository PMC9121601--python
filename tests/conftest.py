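import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """One default synthetic study, generated once per session."""
    from regvar.synthetic_data import ScenarioConfig, generate_regulatory_scenario

    outdir = tmp_path_factory.mktemp("scenario")
    cfg = ScenarioConfig(seed=7)
    files, truth = generate_regulatory_scenario(cfg, outdir)
    return cfg, files, truth
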