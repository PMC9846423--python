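import numpy as np
import pytest

from bsptrace.reference import ReferenceRegion
from bsptrace.synthetic import SimParams, make_reference
from bsptrace.trace_io import ChromatogramTrace


@pytest.fixture(scope="session")
def small_ref() -> ReferenceRegion:
    """400 bp reference with 6 CpG sites well away from the read ends."""
    return make_reference(name="synthRegion", length=400, n_cpg=6, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, L=None) -> ChromatogramTrace:
    """A random trace with a mix of clean and noisy stretches."""
    if L is None:
        L = int(rng.integers(5, 201))
    bases = "".join(rng.choice(list("ACGT"), L))
    phred = rng.integers(0, 61, L)
    # heights: mostly one dominant channel, some mixed bases
    heights = rng.integers(0, 80, (L, 4))
    dominant = rng.integers(0, 4, L)
    clean = rng.random(L) < 0.7
    heights[np.arange(L)[clean], dominant[clean]] = rng.integers(
        500, 1500, clean.sum())
    return ChromatogramTrace("rnd", bases, phred, heights)


def clean_trace(L=200, phred=60, scale=1000) -> ChromatogramTrace:
    """Uniformly high-quality trace with pure single peaks."""
    rng = np.random.default_rng(0)
    idx = rng.integers(0, 4, L)
    bases = "".join("ACGT"[i] for i in idx)
    heights = np.zeros((L, 4), dtype=int)
    heights[np.arange(L), idx] = scale
    return ChromatogramTrace("clean", bases, np.full(L, phred), heights)
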