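import numpy as np
import pytest

from ss8pred.io import ChainRecord, ProfileMatrix


def one_hot_profile(chain: ChainRecord) -> ProfileMatrix:
    """Profile whose rows are the one-hot of each residue ('X' -> uniform)."""
    from ss8pred.alphabets import AA_INDEX, N_AA

    freqs = np.zeros((len(chain), N_AA))
    for i, aa in enumerate(chain.sequence):
        if aa in AA_INDEX:
            freqs[i, AA_INDEX[aa]] = 1.0
        else:
            freqs[i] = 1.0 / N_AA
    return ProfileMatrix(chain.chain_id, freqs)


@pytest.fixture
def aa_hh_corpus():
    """The minimal hand-countable corpus: one chain 'AA' labeled 'HH'."""
    chain = ChainRecord("aa", "AA", "HH")
    return [(chain, one_hot_profile(chain))]


@pytest.fixture
def small_bundle():
    """A small seeded synthetic corpus used by several module tests."""
    from ss8pred.synthetic import GeneratorConfig, generate_corpus

    cfg = GeneratorConfig(n_chains=12, length_range=(40, 60), seed=42)
    return generate_corpus(cfg)
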