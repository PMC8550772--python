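import numpy as np
import pytest

import rollcirc as rc
from rollcirc.align import GenomeIndex


@pytest.fixture(scope="session")
def small_world():
    """A 100 kb single-chromosome genome with genes and mixed-class truths."""
    genome = rc.make_genome(1, 100_000, 0.0, seed=7)
    genome, ann = rc.make_annotation(genome, n_genes=8, seed=3)
    genome, truths = rc.make_circ_truth(
        genome, ann,
        {"exonic": 4, "nss": 2, "intergenic": 2, "intronic": 1, "antisense": 1},
        seed=5,
    )
    return genome, ann, truths


@pytest.fixture(scope="session")
def indexed_world(small_world):
    genome, ann, truths = small_world
    return genome, ann, truths, GenomeIndex(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
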