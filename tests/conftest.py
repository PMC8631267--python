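import pytest

import causalgen as cg


@pytest.fixture(scope="session")
def exp1_grammar():
    return cg.exp1_grammar()


@pytest.fixture(scope="session")
def exp1_table(exp1_grammar):
    return cg.enumerate_laws(exp1_grammar)


@pytest.fixture(scope="session")
def exp2_grammar():
    return cg.exp2_grammar()


@pytest.fixture(scope="session")
def exp2_table(exp2_grammar):
    return cg.enumerate_laws(exp2_grammar)


@pytest.fixture(scope="session")
def exp1_sp(exp1_grammar):
    return exp1_grammar.space


@pytest.fixture()
def a1_design():
    return cg.exp1_design("A1", "near-first", feature_order_seed=0)
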