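import pytest
from hypothesis import HealthCheck, settings

from ppimod.pipeline import Pipeline, PipelineConfig
from ppimod.synthetic_data import GroundTruth, generate_scenario, small_config

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    return small_config(rng_seed=1)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, small_cfg):
    d = tmp_path_factory.mktemp("scenario")
    generate_scenario(small_cfg, d, force=True)
    return d


@pytest.fixture(scope="session")
def truth(scenario_dir):
    return GroundTruth.from_json(scenario_dir / "ground_truth.json")


@pytest.fixture(scope="session")
def pipeline(scenario_dir):
    cfg = PipelineConfig.for_scenario(scenario_dir, n_reiterations=300, rng_seed=1)
    return Pipeline(cfg)
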