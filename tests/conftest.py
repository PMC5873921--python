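import numpy as np
import pytest

from bacfinish.contig import Contig
from bacfinish.simulate import SimParams, make_bac_construct, random_dna


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A small but feature-complete construct: 20 kb insert, 4 kb vector."""
    return SimParams(
        seed=101,
        insert_len=20_000,
        vector_len=4_000,
        overlap_len=4_000,
        indel_rate=5.7e-5,
        n_read_pairs=2_000,
    )


@pytest.fixture(scope="session")
def small_construct(small_params):
    return make_bac_construct(small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def random_contig(rng) -> Contig:
    return Contig("rand10k", random_dna(rng, 10_000))
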