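import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_result():
    """12-leaf simulation with zero event rates and zero mutation."""
    from snoevo.simulate import SimulationConfig, run_simulation

    return run_simulation(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def null_pipeline(null_result):
    from snoevo.pipeline import run_pipeline_on_simulation

    return run_pipeline_on_simulation(null_result)


@pytest.fixture(scope="session")
def benchmark_result():
    """The 12-leaf benchmark: seed 42, 2% mutation, all six event kinds."""
    from snoevo.simulate import benchmark_config, run_simulation

    return run_simulation(benchmark_config(42))


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark_result):
    from snoevo.pipeline import run_pipeline_on_simulation

    return run_pipeline_on_simulation(benchmark_result)


@pytest.fixture(scope="session")
def small_ancestor():
    """3-family ancestral cluster reused by scan/annotate/splice tests."""
    from snoevo.simulate import SimulationConfig, build_ancestral_cluster

    return build_ancestral_cluster(SimulationConfig(seed=3, n_snorna_families=3))
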