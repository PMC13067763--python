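import numpy as np
import pytest

from bescreen import amplicon as amp
from bescreen import simulate as sim


@pytest.fixture(scope="session")
def fixtures():
    return sim.fixture_set()


@pytest.fixture(scope="session")
def prep2_reference(fixtures):
    """Amplicon reference built around the copy-number-2 repeat spacer."""
    return amp.build_reference("ACGTACGT", fixtures.prep_spacers[2], "TGG")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
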