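import numpy as np
import pytest

from kinpred import (
    FixtureSpec,
    KineticsRecord,
    PairFeaturizer,
    SyntheticHashEmbedder,
    make_fixture,
)


@pytest.fixture(scope="session")
def embedder():
    """Small deterministic embedder shared across tests."""
    return SyntheticHashEmbedder(protein_token_dim=16, molecule_token_dim=4, seed=7)


@pytest.fixture(scope="session")
def featurizer(embedder):
    return PairFeaturizer(embedder)


@pytest.fixture(scope="session")
def small_fixture():
    """A 400-sample noise-free-ish fixture for fast model tests."""
    return make_fixture(FixtureSpec(n_samples=400, seed=21, noise_sd=0.1))


def make_record(seq="MKV", smiles="CCO", raw=10.0, **kwargs):
    return KineticsRecord(enzyme_sequence=seq, substrate_smiles=smiles, raw_value=raw, **kwargs)


@pytest.fixture
def toy_records():
    return [
        make_record("MKV", "CCO", 1.0),
        make_record("MKA", "CC.O", 3.0),  # multi-component SMILES
        make_record("MKC", "CCN", 0.0),  # non-positive value
        make_record("MKD", "CCC", 100.0),
        make_record("MKE", "CCF", 114.0),
    ]
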