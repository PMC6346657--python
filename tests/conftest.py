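import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20180914)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(1234)


def make_alignment(codes, demes, positions=None):
    """Small helper to build a LabeledAlignment from raw arrays."""
    from steppingstone.simulate import LabeledAlignment

    codes = np.asarray(codes, dtype=np.uint8)
    demes = np.asarray(demes, dtype=np.int64)
    n_demes = int(demes.max()) + 1
    if positions is None:
        positions = np.arange(n_demes, dtype=float)
    ids = [f"s{i}" for i in range(codes.shape[0])]
    return LabeledAlignment(
        codes=codes, ids=ids, deme_of_sample=demes,
        lattice_position=np.asarray(positions, dtype=float),
    )


def seqs_to_codes(seqs):
    from steppingstone.hky import BASE_INDEX

    return np.array([[BASE_INDEX[c] for c in s] for s in seqs], dtype=np.uint8)
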