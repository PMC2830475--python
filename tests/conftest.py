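import warnings

import numpy as np
import pytest

from kinsca.alignment import Alignment
from kinsca.background import swissprot_background


@pytest.fixture(scope="session")
def bg():
    return swissprot_background()


@pytest.fixture
def toy_alignment():
    """Five gap-free sequences with one invariant column (column 2, Trp)."""
    rows = (
        "ACWDE",
        "AGWDE",
        "ACWKE",
        "TCWDE",
        "ACWDN",
    )
    return Alignment(ids=tuple(f"s{i}" for i in range(5)), rows=rows, anchor_index=0)


@pytest.fixture
def random_alignment_factory():
    """Gap-free random alignments of arbitrary small size, seeded."""

    def build(n, L, seed, gap_rate=0.0):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        idx = rng.integers(0, 20, size=(n, L))
        if gap_rate:
            gaps = rng.random((n, L)) < gap_rate
            gaps[0] = False
            idx = np.where(gaps, 20, idx)
        rows = tuple("".join(letters[r]) for r in idx)
        return Alignment(ids=tuple(f"s{i}" for i in range(n)), rows=rows, anchor_index=0)

    return build


@pytest.fixture(autouse=True)
def _silence_small_subset_warning():
    from kinsca.core import SmallSubsetWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSubsetWarning)
        yield
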