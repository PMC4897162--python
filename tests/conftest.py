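import numpy as np
import pytest

import greymarkov as gm
from greymarkov import casestudy


@pytest.fixture(scope="session")
def coal_series() -> gm.TimeSeries:
    return gm.load_fixture("china_coal_1990_2010")


@pytest.fixture(scope="session")
def coal_params(coal_series) -> gm.SCGMParameters:
    return gm.fit(coal_series)


@pytest.fixture(scope="session")
def published_space() -> gm.StateSpace:
    return casestudy.state_space()


@pytest.fixture(scope="session")
def published_ratio_path(published_space):
    """State path from the published actual / amended ratio columns."""
    years = range(1991, 2011)
    actual = casestudy.actual_series()
    ratios = [actual.value_at(y) / casestudy.PUBLISHED_AMENDED[y] for y in years]
    return gm.assign_states(np.asarray(ratios), published_space)
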