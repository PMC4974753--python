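import numpy as np
import pytest

import ssrkit as sk


@pytest.fixture(scope="session")
def planted_genome():
    """100 kb genome with 50 planted loci over all seven classes."""
    return sk.make_ssr_genome(length=100_000, n_loci=50, n_chromosomes=2, seed=101)


@pytest.fixture(scope="session")
def planted_markers(planted_genome):
    seqs, rec = planted_genome
    return sk.design_all(seqs, sk.planted_loci(rec))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
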