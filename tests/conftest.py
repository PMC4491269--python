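import pytest

from stpscan import PeptideSequence
from stpscan.fixtures import FixtureSpec, generate_negatives, generate_positives

# the hand-checked reference chain: cysteines at 2,7,13,16,20,27,
# loops (4,5,2,3,6), a valid motif anchored at C3-C4
TOY_STP = "GCAAAACAAAAACAACAAACAAAAAACGG"


@pytest.fixture
def toy_stp() -> PeptideSequence:
    return PeptideSequence("toy", TOY_STP)


@pytest.fixture(scope="session")
def small_dataset():
    """50/50 synthetic chains, enough for fast classifier tests."""
    spec = FixtureSpec(n_pos=50, n_neg=50, seed=7)
    return generate_positives(spec), generate_negatives(spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size synthetic dataset: 144 positives, 393 negatives."""
    spec = FixtureSpec(seed=11)
    return generate_positives(spec), generate_negatives(spec)
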