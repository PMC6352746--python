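import numpy as np
import pytest

from mitofoot import CircularGenome, CoverageTrack


@pytest.fixture
def small_genome():
    return CircularGenome("mt", 300)


@pytest.fixture
def seq_genome():
    rng = np.random.default_rng(12345)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return CircularGenome("mt", 400, seq)


@pytest.fixture
def uniform_track(small_genome):
    return CoverageTrack(small_genome, np.full(300, 9.0))


def random_intervals(rng, n, L, max_len=60):
    """Random circular intervals as (start, end) pairs, possibly wrapping."""
    out = []
    for _ in range(n):
        s = int(rng.integers(0, L))
        w = int(rng.integers(1, max_len + 1))
        out.append((s, (s + w) % L if (s + w) % L != s else (s + 1) % L))
    return out


def base_set(ivl, L):
    """Brute-force set of bases covered by a circular interval."""
    s, e = ivl
    n = (e - s) % L or (L if (s, e) == (0, L) else 0)
    if (s, e) == (0, L):
        n = L
    return {(s + i) % L for i in range(n)}
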