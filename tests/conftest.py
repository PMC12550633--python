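import numpy as np
import pytest

from holebif.landscape import (
    Cofactor,
    Edge,
    Landscape,
    fig8_landscape,
)
from holebif.rates import RateParameters


@pytest.fixture(scope="session")
def fig8():
    return fig8_landscape()


@pytest.fixture(scope="session")
def table2_params():
    return RateParameters()


@pytest.fixture()
def two_site_landscape():
    """Minimal symmetric toy: two equal-potential relay sites, one edge."""
    return Landscape(
        cofactors=[
            Cofactor("A", "relay", "hot", 1.5),
            Cofactor("B", "relay", "hot", 1.5),
        ],
        edges=[Edge("A", "B", 5.0)],
        rate_params=RateParameters(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
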