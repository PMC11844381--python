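import numpy as np
import pytest

from zdnascan import ScoringParams

# Published worked-example sequences (mouse metallothionein I promoter study)
NATIVE = "GCGCGTGACTATGCGTG"
MUTANT = "GCGCGTGCATATGCGTG"
MODEL = "GACGCGGGGCGCGTGCATATGCGTGG"


@pytest.fixture
def params():
    return ScoringParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


def random_sequence(rng, length):
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def random_score_array(rng, max_len=60):
    """Mixed-sign multiples of 0.25 so float sums are exact in any order."""
    n = rng.integers(0, max_len + 1)
    return (rng.integers(-32, 33, size=n) * 0.25).tolist()
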