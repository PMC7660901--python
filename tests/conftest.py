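import random

import pytest

from pak.fixtures import (
    FixtureSpec,
    SdGeneElement,
    SpaninPairElement,
    make_genome,
)
from pak.model import GenomeSequence


def random_genome(seed: int, length: int) -> GenomeSequence:
    rng = random.Random(seed)
    return GenomeSequence(
        id=f"rand{seed}", seq="".join(rng.choice("ACGT") for _ in range(length))
    )


@pytest.fixture(scope="session")
def sd_fixture():
    """A genome with one planted gene carrying an S-D motif at offset 7."""
    return make_genome(
        FixtureSpec(seed=11, genome_len=1500, elements=(SdGeneElement(sd_offset=7),))
    )


@pytest.fixture(scope="session")
def embedded_pair_fixture():
    return make_genome(
        FixtureSpec(
            seed=21,
            genome_len=2500,
            elements=(SpaninPairElement(architecture="embedded"),),
        )
    )
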