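import numpy as np
import pytest

from ecoc_tka.codes import CodeBook, build_hadamard_matrix


@pytest.fixture(scope="session")
def hadamard16_codebook() -> CodeBook:
    """All 16 rows of the order-16 Hadamard matrix as a 16-class codebook.

    The first column is constant zero, so 15 bits are active and the minimum
    pairwise distance is 8 (t = 3 correctable errors).
    """
    m = build_hadamard_matrix(16)
    return CodeBook("hadamard", 16, list(range(16)), m)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
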