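import logging

import numpy as np
import pytest

from geotree_le.synthetic import SyntheticTruth, make_panel


@pytest.fixture(autouse=True)
def _quiet_logging():
    # fallback warnings (unseen group levels etc.) are part of the contract
    # but would swamp simulation-test output
    logging.getLogger("geotree_le").setLevel(logging.ERROR)
    yield
    logging.getLogger("geotree_le").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth()


@pytest.fixture(scope="session")
def default_panel(default_truth):
    """The stated world: 31 regions x 3 decadal years."""
    return make_panel(default_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
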