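import numpy as np
import pytest

from hairpinrule.genome_io import GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ac_background(rng, n):
    """Background over {A, C} only: A pairs T and C pairs G, so an A/C
    string can contain no base pair at all — guaranteed palindrome-free."""
    return "".join(rng.choice(["A", "C"], size=n, p=[0.6, 0.4]))


@pytest.fixture
def planted_genome(rng):
    """200 nt pairing-free background with one perfect stem-10/loop-3 site
    planted at offset 50."""
    site = "GACGTACGTA" + "AAA" + "TACGTACGTC"
    bg = ac_background(rng, 200)
    seq = bg[:50] + site + bg[50:]
    return GenomeRecord("planted", seq, circular=False), 50
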