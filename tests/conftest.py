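import numpy as np
import pytest

from nanofshd.feature_library import synth_feature_set

#: fixed a-priori seed used by the stochastic tests
SEED = 20240513

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@pytest.fixture(scope="session")
def library():
    """Full-size synthetic feature library (3.3 kb unit)."""
    return synth_feature_set(seed=7)


@pytest.fixture(scope="session")
def small_library():
    """Scaled-down library (400 bp unit) for fast alignment tests."""
    return synth_feature_set(
        unit_len=400, anchor_lens={"D4F104S1": 300, "pLAM": 200}, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def random_seq(n, rng):
    return BASES[rng.integers(0, 4, n)]


def mutate_subs(seq, rate, rng):
    """Substitution-only mutation (keeps coordinates)."""
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    idx = np.searchsorted(BASES, out[mask])
    out[mask] = BASES[(idx + 1 + rng.integers(0, 3, int(mask.sum()))) % 4]
    return out
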