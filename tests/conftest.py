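import numpy as np
import pytest

from phyloniche.alignment import Alignment, PopulationAssignment


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_sequences(
        ["s1", "s2", "s3", "s4"],
        ["ACGT", "ACGT", "ACGA", "ATGA"],
    )


@pytest.fixture
def two_pop_assignment() -> PopulationAssignment:
    return PopulationAssignment(
        {"s1": "north", "s2": "north", "s3": "south", "s4": "south"}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
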