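import numpy as np
import pytest

from chromalign import Genome, GenomeSequence, build_index
from chromalign.minimizer_index import MinimizerParams

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    rng = np.random.default_rng(42)
    return Genome(
        [
            GenomeSequence("chr1", random_seq(rng, 20_000)),
            GenomeSequence("chr2", random_seq(rng, 12_000)),
        ]
    )


@pytest.fixture(scope="session")
def toy_index(toy_genome):
    return build_index(toy_genome, MinimizerParams())
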