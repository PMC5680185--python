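import numpy as np
import pytest

from phylorder.genome_io import Genome, GenomeSet


@pytest.fixture
def table_pair() -> GenomeSet:
    """The two-genome worked example used throughout the docs."""
    return GenomeSet([
        Genome("Genome1", [[1, -2, 3, 4]]),
        Genome("Genome2", [[1, 2, 3, 4, -5]]),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genome(rng, n_genes: int, n_chromosomes: int = 2,
                  name: str = "G") -> Genome:
    """A random signed permutation split into chromosomes."""
    perm = rng.permutation(np.arange(1, n_genes + 1))
    signs = rng.choice([1, -1], n_genes)
    genes = [int(p * s) for p, s in zip(perm, signs)]
    bounds = sorted(rng.choice(np.arange(1, n_genes), n_chromosomes - 1,
                               replace=False)) if n_chromosomes > 1 else []
    chroms = []
    prev = 0
    for b in list(bounds) + [n_genes]:
        chroms.append(genes[prev:b])
        prev = b
    return Genome(name, [c for c in chroms if c])
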