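import numpy as np
import pytest

from admixkit import FrequencyPanel


def make_panel(freqs, pops, counts=None, blocks=None):
    """Small panel builder for hand-computed examples."""
    freqs = np.asarray(freqs, dtype=float)
    S, P = freqs.shape
    if counts is None:
        counts = np.full((S, P), 100, dtype=np.int64)
    else:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim == 0:
            counts = np.full((S, P), int(counts), dtype=np.int64)
    if blocks is None:
        blocks = np.zeros(S, dtype=int)
    return FrequencyPanel(
        snp_ids=np.array([f"s{i}" for i in range(S)]),
        chrom=np.repeat("1", S),
        pos=(np.arange(S) + 1) * 100,
        freqs=freqs,
        counts=counts,
        blocks=np.asarray(blocks),
        pop_names=list(pops),
    )


def random_panel(rng, n_snps=60, pops=("A", "B", "C", "D"), n_blocks=4):
    """Random dense panel; frequencies iid uniform (no model implied)."""
    S, P = n_snps, len(pops)
    return make_panel(
        rng.uniform(0.0, 1.0, (S, P)),
        pops,
        counts=rng.integers(4, 40, (S, P)) * 2,
        blocks=(np.arange(S) * n_blocks) // S,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_panel():
    """The three-site quartet used in the worked examples."""
    freqs = np.array(
        [
            [0.5, 0.1, 0.4, 0.2],
            [0.2, 0.2, 0.8, 0.6],
            [0.9, 0.3, 0.5, 0.5],
        ]
    )
    return make_panel(freqs, ["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def mixe_panel():
    """Moderate-size quartet panel simulated under the admixed-Mixe history."""
    from admixkit import paper_fixture, simulate_panel

    return simulate_panel(paper_fixture("quartet_mixe", n_snps=40_000, n_blocks=40, seed=42))
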