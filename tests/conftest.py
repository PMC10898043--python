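import numpy as np
import pytest

import rrmp


@pytest.fixture(scope="session")
def standard_genome():
    """The standard synthetic genome: AT-rich background, GC-rich islands."""
    return rrmp.simulate_genome(seed=11)


@pytest.fixture(scope="session")
def small_genome():
    return rrmp.simulate_genome(n_islands=8, seed=5)


@pytest.fixture(scope="session")
def converted_library(small_genome):
    genome, annotations, profile = small_genome
    fragments = rrmp.fragment_genome(genome, n_fragments=6000, seed=6)
    molecules = rrmp.convert_library(fragments, genome, profile,
                                     rrmp.ConversionParams(seed=7))
    molecules, _ = rrmp.filter_non_conversion(molecules)
    return molecules


def random_sequence(rng: np.random.Generator, length: int,
                    alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
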