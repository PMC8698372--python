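import numpy as np
import pytest

from sdpscan import (
    Alignment,
    SyntheticSpec,
    generate,
    load_builtin_scales,
    load_mclachlan,
)


@pytest.fixture(scope="session")
def scales():
    return load_builtin_scales()


@pytest.fixture(scope="session")
def mclachlan():
    return load_mclachlan()


@pytest.fixture(scope="session")
def channels(mclachlan, scales):
    """The full 18-channel set: substitution matrix + 17 property scales."""
    return [mclachlan] + list(scales)


@pytest.fixture
def toy_alignment():
    """3 proteins x 4 columns, gap-free, hand-checkable."""
    return Alignment(ids=("p1", "p2", "p3"), rows=("AVLD", "AVID", "GVLE"))


@pytest.fixture
def synthetic_alignment():
    """Default planted-SDP alignment (15 sequences x 50 columns, seed 7)."""
    return generate(SyntheticSpec(seed=7))


def random_alignment(rng, n_min=3, n_max=6, len_max=10, gap_prob=0.2):
    """A small random alignment with random gaps, for oracle comparisons."""
    from sdpscan.scales import AMINO_ACIDS

    n = int(rng.integers(n_min, n_max + 1))
    length = int(rng.integers(1, len_max + 1))
    symbols = np.array(list(AMINO_ACIDS + "-"))
    probs = np.full(21, (1 - gap_prob) / 20)
    probs[20] = gap_prob
    grid = rng.choice(symbols, size=(n, length), p=probs)
    return Alignment(
        ids=tuple(f"p{i}" for i in range(n)),
        rows=tuple("".join(r) for r in grid),
    )
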