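import numpy as np
import pytest

from mutspec.genome import generate_genome


@pytest.fixture(scope="session")
def toy_genome():
    """Small annotated genome shared by read-only tests."""
    return generate_genome(
        n_contigs=1, contig_length=20_000, n_genes=4, gc_content=0.40, seed=7
    )


@pytest.fixture(scope="session")
def intron_genome():
    """Genome in which every gene carries one intron."""
    return generate_genome(
        n_contigs=1,
        contig_length=20_000,
        n_genes=4,
        gc_content=0.40,
        seed=11,
        intron_fraction=1.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
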