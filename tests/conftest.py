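import numpy as np
import pytest
from hypothesis import settings

from snpmine.pileup import PositionStack

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_stack(counts, ref_base="A", ref_id="chr1", pos=1):
    """PositionStack from a partial base->count mapping."""
    full = {b: counts.get(b, 0) for b in "ACGT"}
    return PositionStack(
        ref_id=ref_id, pos=pos, ref_base=ref_base, counts=full, depth=sum(full.values())
    )


@pytest.fixture
def stack_factory():
    return make_stack
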