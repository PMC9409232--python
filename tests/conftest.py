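import random

import pytest

from mitocms.genome import CircularSequence
from mitocms.synthetic import GeneratorConfig, generate_genome_pair


def random_seq(n, seed=None, rng=None):
    r = rng or random.Random(seed)
    return "".join(r.choice("ACGT") for _ in range(n))


SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def sense_cds(n_codons, seed=None, rng=None):
    """A valid CDS: ATG, sense codons, one terminal stop."""
    r = rng or random.Random(seed)
    return "ATG" + "".join(r.choice(SENSE_CODONS) for _ in range(n_codons - 2)) + "TAA"


@pytest.fixture(scope="session")
def default_pair():
    """One default synthetic genome pair shared by read-only tests."""
    return generate_genome_pair(GeneratorConfig(seed=1))


@pytest.fixture
def tiny_circular():
    return CircularSequence("tiny", "ACGTACGTAA", circular=True)
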