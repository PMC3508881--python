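import pytest

from assertnet import fixtures as fx
from assertnet.vocabulary import compile_matcher


@pytest.fixture(scope="session")
def table_vocab():
    return fx.load_table_vocabulary()


@pytest.fixture(scope="session")
def protein_vocab():
    return fx.load_protein_vocabulary()


@pytest.fixture(scope="session")
def vocab():
    """Table-1 style vocabulary merged with the 25-protein vocabulary."""
    return fx.default_vocabulary()


@pytest.fixture(scope="session")
def golden_vocab():
    """Default vocabulary plus the synthetic filler proteins."""
    return fx.golden_vocabulary()


@pytest.fixture(scope="session")
def relations():
    return fx.load_default_relations()


@pytest.fixture(scope="session")
def matcher(vocab):
    return compile_matcher(vocab)


@pytest.fixture(scope="session")
def golden_matcher(golden_vocab):
    return compile_matcher(golden_vocab)


@pytest.fixture(scope="session")
def golden_net():
    return fx.golden_network()


@pytest.fixture(scope="session")
def derivation_config():
    return fx.golden_derivation_config()
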