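import pytest

from basinflood.fixtures import L1_ENERGIES, L2_ENERGIES, chain_landscape
from basinflood.landscape import RnaLandscape

#: short sequences whose full landscapes are enumerated exhaustively in tests
FIXTURE_SEQUENCES = [
    "AAAA",
    "GCGC",
    "GGGAAACCC",
    "ACGUACGUACGU",
    "GGCGAAAGGCCAAGGC",
    "GCGCGCAAAGCGCGCAAAGC",
    "UUGGAGUACACAACCUGUAC",
]


@pytest.fixture
def L1():
    """3-state path s0(0.0)-s1(2.0)-s2(1.0): two basins {s0,s1} and {s2}."""
    return chain_landscape(L1_ENERGIES)


@pytest.fixture
def L2():
    """5-state path with basins {s0,s1}, {s2}, {s3,s4} and saddles at 2.0/3.0."""
    return chain_landscape(L2_ENERGIES)


@pytest.fixture
def hairpin9():
    return RnaLandscape("GGGAAACCC")
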