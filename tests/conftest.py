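import math

import pytest

from ontosim import fixture_toy9, information_content


@pytest.fixture(scope="session")
def toy9():
    return fixture_toy9()


@pytest.fixture(scope="session")
def toy9_ic(toy9):
    return information_content(toy9.dag, toy9.corpus, math.e)
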