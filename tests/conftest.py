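import pytest

from targetome.synthetic_data import (
    SimulationConfig,
    generate_genome,
    simulate_clip_reads,
    simulate_rnaseq,
    simulate_small_rna,
)


@pytest.fixture(scope="session")
def dataset():
    return generate_genome(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def clip(dataset):
    """(reads, per-read truth) for the shared dataset."""
    return simulate_clip_reads(dataset, seed=101)


@pytest.fixture(scope="session")
def rnaseq(dataset):
    return {c: simulate_rnaseq(dataset, c, seed=201 + i) for i, c in enumerate(("control", "knockdown"))}


@pytest.fixture(scope="session")
def small_rna(dataset):
    return {c: simulate_small_rna(dataset, c, seed=301 + i) for i, c in enumerate(("control", "knockdown"))}
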