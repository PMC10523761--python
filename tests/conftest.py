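import pytest

from modulimpact import BenchmarkConfig, generate_benchmark
from modulimpact.pipeline import PipelineParams, run_on_bundle


@pytest.fixture(scope="session")
def default_config():
    """The study-condition benchmark: 2000 genes, 12 planted terms,
    35% planted impact over an 8% background alteration rate, seed 1."""
    return BenchmarkConfig(seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return generate_benchmark(default_config)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full pipeline run on the default benchmark (1000-randomization FDR)."""
    return run_on_bundle(default_bundle, PipelineParams(seed=1, n_rand=1000))


@pytest.fixture(scope="session")
def null_config():
    """A fully null benchmark: no planted impact and no tissue-biased
    background terms."""
    return BenchmarkConfig(seed=1, planted_terms=0, expressed_background_fraction=0.0)


@pytest.fixture(scope="session")
def null_bundle(null_config):
    return generate_benchmark(null_config)


@pytest.fixture(scope="session")
def null_result(null_bundle):
    return run_on_bundle(null_bundle, PipelineParams(seed=1, n_rand=1000))


@pytest.fixture(scope="session")
def small_config():
    """A fast, smaller benchmark for structural tests."""
    return BenchmarkConfig(
        n_genes=500,
        n_terms=20,
        planted_terms=4,
        planted_term_size=(12, 25),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_benchmark(small_config)
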