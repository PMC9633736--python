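from itertools import product

import pytest

from seqreduce import enumerate_restricted, get_hpc, get_identity, get_worked_example, revcomp


@pytest.fixture(scope="session")
def hpc():
    return get_hpc()


@pytest.fixture(scope="session")
def identity():
    return get_identity()


@pytest.fixture(scope="session")
def worked_example():
    return get_worked_example()


@pytest.fixture(scope="session")
def representatives():
    """All 2135 order-2 restricted-SSR representatives, in enumeration order."""
    return list(enumerate_restricted(2))


@pytest.fixture(scope="session")
def dna_strings_to_8():
    """Every DNA string of length 2..8, paired with its reverse complement."""
    strings = ["".join(p) for L in range(2, 9) for p in product("ACGT", repeat=L)]
    return [(s, revcomp(s)) for s in strings]
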