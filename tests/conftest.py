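import numpy as np
import pytest

from tandemkit.seqio import LongRead
from tandemkit.synth import random_monomer


@pytest.fixture
def monomer120() -> str:
    """A fixed 120-bp monomer with a duplicate-free cyclic 12-mer spectrum."""
    return random_monomer(120, 0.60, 1)


@pytest.fixture
def perfect_array_read(monomer120) -> LongRead:
    """Eight exact copies of the 120-bp monomer, no flanks."""
    return LongRead("r1", "r1", monomer120 * 8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
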