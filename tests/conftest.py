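import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pirnakit.io_formats import SequenceLibrary, SmallRNARecord
from pirnakit.synthetic_fixtures import make_transposons, plant_positive_reads

from oracles import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_library(rng):
    """50 random records with random lengths for round-trip tests."""
    records = [
        SmallRNARecord(id=f"r{i:03d}", sequence=random_dna(rng, int(rng.integers(20, 36))))
        for i in range(50)
    ]
    return SequenceLibrary(records, source_tag="random")


@pytest.fixture(scope="session")
def toy_transposons():
    return make_transposons(n=10, length=400, seed=11)


@pytest.fixture(scope="session")
def toy_positives(toy_transposons):
    return plant_positive_reads(toy_transposons, n=60, mismatch_rate=0.2, seed=12)
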