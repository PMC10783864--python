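import numpy as np
import pytest

from lysptm.segments import AMINO_ACIDS, Dataset


def random_segments(rng: np.random.Generator, n: int, half_width: int) -> list[str]:
    """Random valid segments: iid residues with a forced center lysine."""
    width = 2 * half_width + 1
    out = []
    for _ in range(n):
        chars = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), width)]
        chars[half_width] = "K"
        out.append("".join(chars))
    return out


def random_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.where(rng.random((n, 4)) < 0.3, 1, -1).astype(np.int8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_dataset(rng):
    """Small random dataset (30 records, L=4, 6 proteins)."""
    n, L = 30, 4
    segs = random_segments(rng, n, L)
    labels = random_labels(rng, n)
    pids = [f"P{i % 6}" for i in range(n)]
    return Dataset(pids, np.arange(1, n + 1) * 10, segs, labels, L)
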