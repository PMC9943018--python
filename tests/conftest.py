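import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default simulation: 10 genomes, ~2,000 genes, ~300 planted
    riboswitches, decoys at 0.3, 7 tandem pairs."""
    from riboscreen.simulate import SimulationConfig, generate

    root = tmp_path_factory.mktemp("bundle")
    bundle, truth = generate(SimulationConfig(seed=20_260_101), root / "sim")
    return bundle, truth


@pytest.fixture(scope="session")
def default_pipeline(default_bundle, tmp_path_factory):
    from riboscreen.pipeline import PipelineConfig, run_all

    bundle, truth = default_bundle
    out = tmp_path_factory.mktemp("results")
    result = run_all(bundle.root, PipelineConfig(out_dir=str(out / "run")))
    return bundle, truth, result
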