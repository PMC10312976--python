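import pytest

from lariatseq.align import Read
from lariatseq.simulate import SimulationConfig, make_toy_genome, simulate_reads


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=5, introns_per_gene=3,
                            error_rate=0.0, n_lariat_reads=60,
                            n_linear_reads=60, n_circle_reads=10,
                            u12_fraction=0.2)


@pytest.fixture(scope="session")
def toy_bundle(small_config):
    return make_toy_genome(small_config)


@pytest.fixture(scope="session")
def toy_reads(small_config, toy_bundle):
    reads, truth = simulate_reads(toy_bundle, small_config)
    return [Read(rid, seq) for rid, seq in reads], truth.set_index("read_id")
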