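import numpy as np
import pytest

from imprintscan import SimulationConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=40)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    """(records_a, records_b, truth) for a 40-gene synthetic transcriptome."""
    return simulate_transcriptome(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_transcript(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T sequence (sites occur by chance)."""
    return "".join(rng.choice(list("ACGT"), size=length))
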