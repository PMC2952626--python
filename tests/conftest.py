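import numpy as np
import pytest

from lhgr.zcurve import build_curve


@pytest.fixture
def rng():
    return np.random.default_rng(20100)


@pytest.fixture
def two_block_curve():
    """1 kb pure-AT followed by 1 kb pure-GC."""
    return build_curve("AT" * 500 + "GC" * 500)


def random_sequence(rng, n, p_gc=0.5, p_n=0.0):
    """I.i.d. test sequence with optional N contamination."""
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    p = [(1 - p_gc) * (1 - p_n) / 2, p_gc * (1 - p_n) / 2,
         p_gc * (1 - p_n) / 2, (1 - p_gc) * (1 - p_n) / 2, p_n]
    arr = bases[rng.choice(5, size=n, p=p)]
    return arr.tobytes().decode("ascii")
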