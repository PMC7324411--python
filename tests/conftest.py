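import random

import pytest

from evocount.io import FastqRecord


@pytest.fixture
def rng():
    return random.Random(20260926)


def random_record(rng: random.Random, length: int, read_id: str = "r") -> FastqRecord:
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    qual = tuple(rng.randint(0, 41) for _ in range(length))
    return FastqRecord(read_id, seq, qual)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
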