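import numpy as np
import pytest

from motifclust.pfm import PFM, prepare


def random_pfm(rng, pfm_id, length=None, lo=5, hi=12, sharp=0.3):
    """A random normalized+trimmed PFM with a guaranteed informative core."""
    if length is None:
        length = int(rng.integers(lo, hi + 1))
    probs = rng.dirichlet(np.full(4, sharp), size=length).T
    # anchor the ends so trimming keeps the full length
    for j in (0, length - 1):
        col = np.full(4, 0.05)
        col[rng.integers(4)] = 0.85
        probs[:, j] = col
    counts = np.round(probs * 100)
    counts[:, counts.sum(axis=0) == 0] = 1
    return prepare(PFM(id=pfm_id, counts=counts, n_sites=100))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_pfm():
    """Factory: PFM from explicit probability columns (already normalized)."""

    def _make(pfm_id, columns, **kw):
        probs = np.array(columns, dtype=float).T
        return PFM(id=pfm_id, counts=probs.copy(), probs=probs, **kw)

    return _make
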