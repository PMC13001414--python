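import numpy as np
import pytest

from idpensemble.variants import PeptideSequence


@pytest.fixture(scope="session")
def wild_type() -> PeptideSequence:
    return PeptideSequence("MEVQLGLGRVYPRPP", label="MLP_wt")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
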