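import pytest

from dirseq.simulate import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def toy_world():
    """A 30-gene synthetic genome with seeded AS isoforms and DIR truth."""
    cfg = SimulationConfig(n_genes=30, seed=3)
    sequences, genes, manifest = make_genome(cfg)
    return sequences, genes, manifest
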