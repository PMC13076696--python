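import pytest

from increclm.chem_io import build_vocabulary
from increclm.clm_engine import ModelConfig, build_model
from increclm.toyworld import (
    build_toy_benchmark,
    generate_toy_universe,
)


@pytest.fixture(scope="session")
def toy_universe():
    return generate_toy_universe(seed=3)


@pytest.fixture(scope="session")
def toy_benchmark(toy_universe):
    return build_toy_benchmark(
        toy_universe, series_size=60, corpus_size=2000, seed=5
    )


@pytest.fixture(scope="session")
def toy_vocab(toy_benchmark):
    return build_vocabulary(
        [m.smiles_canonical for m in toy_benchmark.pretrain_corpus]
        + toy_benchmark.series.smiles
    )


@pytest.fixture(scope="session")
def tiny_vocab():
    return build_vocabulary(
        ["CCO", "CCN", "c1ccccc1", "Clc1ccccc1", "CC(=O)O", "CS(N)(=O)=O"]
    )


@pytest.fixture()
def tiny_model(tiny_vocab):
    config = ModelConfig(
        vocab=tiny_vocab, embedding_dim=8, recurrent_layers=(12,),
        use_batchnorm=True, dropout=0.0, batch_size=8,
    )
    return build_model(config, seed=0)
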