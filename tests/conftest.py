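import pytest

from beltrace.corpus import build_index
from beltrace.lexicons import EntityLexicon
from beltrace.simulate import GeneratorParams, generate_corpus, generate_relation_dataset


@pytest.fixture(scope="session")
def synthetic():
    """Default-parameter synthetic study (50 statements), fixed seed."""
    return generate_corpus(GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def synthetic_index(synthetic):
    return build_index(synthetic.documents)


@pytest.fixture(scope="session")
def relation_data():
    return generate_relation_dataset(GeneratorParams(seed=0))


@pytest.fixture()
def tnf_lexicon():
    lex = EntityLexicon()
    lex.add("HGNC", "TNF", "tumor necrosis factor")
    lex.add("HGNC", "TNF", "TNF-alpha")
    lex.add("HGNC", "CREB1", "cAMP responsive element binding protein 1")
    return lex
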