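import numpy as np
import pytest

from mitorecomb import CircularGenome, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.435) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def plant(rng, length, layout):
    """Build a circular genome from a layout of ('bg', n) and ('seq', s) parts.

    Returns the genome; callers track coordinates themselves.
    """
    parts = []
    for kind, val in layout:
        parts.append(random_seq(rng, val) if kind == "bg" else val)
    seq = "".join(parts)
    assert len(seq) == length
    return CircularGenome("fixture", seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20220921)


@pytest.fixture
def direct_toy(rng):
    """1,200 bp circle with a 120 bp direct repeat at 100 and 700.

    Layout: [0,100) bg | [100,220) R | [220,700) bg | [700,820) R | [820,1200) bg
    """
    R = random_seq(rng, 120)
    genome = plant(rng, 1200, [("bg", 100), ("seq", R), ("bg", 480),
                               ("seq", R), ("bg", 380)])
    return genome, R, (100, 220), (700, 820)


@pytest.fixture
def inverted_toy(rng):
    """1,200 bp circle with a 120 bp inverted repeat at 100 and 700."""
    R = random_seq(rng, 120)
    genome = plant(rng, 1200, [("bg", 100), ("seq", R), ("bg", 480),
                               ("seq", revcomp(R)), ("bg", 380)])
    return genome, R, (100, 220), (700, 820)
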