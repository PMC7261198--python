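import numpy as np
import pytest

from h1ntd.model import ModelParameters
from h1ntd.sequences import extract_basic_subregion, load_bundled_ntds


@pytest.fixture(scope="session")
def ntds():
    """The three bundled NTD subtype sequences keyed by subtype id."""
    return {s.subtype_id: s for s in load_bundled_ntds()}


@pytest.fixture(scope="session")
def subregions(ntds):
    """Basic-subregion sequences per subtype (span-first-to-last-basic)."""
    return {k: extract_basic_subregion(s) for k, s in ntds.items()}


@pytest.fixture
def neutral_params():
    return ModelParameters(neutralized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
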