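import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario_bundle(tmp_path_factory):
    """A small synthetic scenario, generated once per session."""
    from edgotype import synthetic

    outdir = tmp_path_factory.mktemp("scenario")
    scenario = synthetic.SyntheticScenario(seed=3)
    return synthetic.generate_scenario(scenario, outdir)


@pytest.fixture(scope="session")
def pipeline_result(scenario_bundle):
    """Full pipeline run on the session scenario."""
    from edgotype import pipeline

    cfg = pipeline.PipelineConfig.for_scenario_dir(scenario_bundle.outdir)
    return pipeline.run_pipeline(cfg)
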