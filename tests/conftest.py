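import random

import pytest

from oligoms.chem_core import default_registry
from oligoms.sequence_db import FastaRecord


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_fasta_records(n, length, seed, prefix="seq"):
    r = random.Random(seed)
    return [
        FastaRecord(f"{prefix}{i}", "",
                    "".join(r.choice("ACGU") for _ in range(length)))
        for i in range(n)
    ]


@pytest.fixture
def small_db():
    return random_fasta_records(3, 120, seed=11)
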