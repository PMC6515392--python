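import numpy as np
import pytest

from spikenose import (
    GeneratorConfig,
    RankOrderPattern,
    run_experiment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rank_pattern(rng) -> RankOrderPattern:
    return RankOrderPattern(rng.permutation(16))


@pytest.fixture(scope="session")
def bench_experiment():
    """The full synthetic bench experiment at the default study conditions
    (shared read-only across tests; ~285 streamed frames)."""
    return run_experiment(GeneratorConfig(seed=0))


@pytest.fixture
def small_generator_config():
    """A reduced dataset for fast module-level pipeline tests."""
    return GeneratorConfig(
        samples_per_class={
            "ammonia": 8,
            "acetaldehyde": 8,
            "acetone": 8,
            "ethylene": 8,
            "ethanol": 8,
            "toluene": 8,
        },
        seed=7,
    )
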