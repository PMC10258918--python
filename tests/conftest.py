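import numpy as np
import pytest

from cellfract import BoundaryConfig, RunConfig
from cellfract.synthetic import FixtureSpec, make_gap_closure_series

# gap-closure fixtures use 10 px cell spacing, so contact is declared at
# 1.5 cell diameters rather than the dense-monolayer default
SPARSE_CONTACT = 15.0


@pytest.fixture(scope="session")
def gap_series_sharp():
    """Amplitude-0 gap closure: straight post-contact boundary, contact at 5."""
    spec = FixtureSpec(kind="gap_closure", shape=(256, 256), params={"frames": 12}, seed=0)
    return make_gap_closure_series(spec)


@pytest.fixture(scope="session")
def gap_series_fingered():
    """Strongly interdigitated gap closure (amplitude 42 px, wavelength 40 px)."""
    spec = FixtureSpec(
        kind="gap_closure",
        shape=(256, 256),
        params={"frames": 12, "amplitude": 42, "wavelength": 40},
        seed=0,
    )
    return make_gap_closure_series(spec)


@pytest.fixture
def sparse_config():
    return RunConfig(contact_threshold=SPARSE_CONTACT)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
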