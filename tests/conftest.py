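import numpy as np
import pytest
from hypothesis import settings

from glk.sequence_io import SequenceRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20150928)


@pytest.fixture
def random_records(rng):
    """Ten random sequences, 200-2000 bp, with occasional N runs."""
    records = []
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    for i in range(10):
        n = int(rng.integers(200, 2000))
        arr = bases[rng.choice(5, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04])]
        records.append(SequenceRecord(f"seq{i}", arr.tobytes().decode("ascii")))
    return records


def random_dna(rng, n, gc=0.5):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")
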