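import numpy as np
import pytest

from copyvar import synth
from copyvar.preprocess import ReadRecord

TOY_REGIONS = {"18S": 10, "ITS1": 5, "5.8S": 5, "ITS2": 5, "26S": 10}


@pytest.fixture(scope="session")
def toy_locus():
    """35 bp locus with the five-region layout."""
    return synth.make_locus(TOY_REGIONS, seed=11)


@pytest.fixture(scope="session")
def small_locus():
    """300 bp locus used for read-level pipeline tests."""
    return synth.make_locus(
        {"18S": 80, "ITS1": 40, "5.8S": 40, "ITS2": 40, "26S": 100}, seed=5
    )


def alt_base(locus: str, position: int, offset: int = 1) -> str:
    """A base different from the locus base at a 1-based position."""
    b = locus[position - 1]
    return "ACGT"[("ACGT".index(b) + offset) % 4]


def read(bases: str, q: int = 40, rid: str = "r") -> ReadRecord:
    return ReadRecord(rid, bases, tuple([q] * len(bases)))


@pytest.fixture(scope="session")
def planted_sample(small_locus):
    """Pool + reads with three variants planted at frequency 0.30, no error."""
    locus, regions = small_locus
    positions = (60, 150, 240)
    variants = [synth.VariantSpec(p, alt_base(locus, p), 0.30) for p in positions]
    pool = synth.make_copy_pool(locus, variants, n_copies=200, seed=6)
    reads = synth.sequence_reads(
        pool, synth.ReadSimParams(coverage=200, read_length=80, error_rate=0.0, seed=7)
    )
    return locus, regions, variants, pool, reads
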