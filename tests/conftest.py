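import numpy as np
import pytest

from cpdesign.synthetic import SITE_SCORES, synthetic_apical_domain


@pytest.fixture(scope="session")
def ad_domain():
    """Synthetic 192-333-numbered domain with the canonical glycine layout."""
    record, _, _ = synthetic_apical_domain()
    return record


@pytest.fixture(scope="session")
def ad_ss():
    _, ss, _ = synthetic_apical_domain()
    return ss


@pytest.fixture(scope="session")
def ad_profile():
    _, _, profile = synthetic_apical_domain()
    return profile


@pytest.fixture(scope="session")
def table1_scores():
    """Published per-site disorder scores at the six cleavage sites."""
    return dict(SITE_SCORES)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240201)
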