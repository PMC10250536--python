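import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from driverscan import GenomeSequence, RegionSet, Interval


@pytest.fixture
def toy_genome():
    # 40 bp with mixed composition and an internal N
    return GenomeSequence({"chr1": "ACGTACGTAAGGCCTTACGTNACGTACGTTTAACCGGATC"})


@pytest.fixture
def poly_a_genome():
    return GenomeSequence({"t": "A" * 12})


def region(*triples):
    return RegionSet(Interval(c, s, e) for c, s, e in triples)


@pytest.fixture
def make_region():
    return region
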