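import pytest

from streetscape import sampler
from streetscape.synthetic_city import CityConfig, gen_city, render_summaries


@pytest.fixture(scope="session")
def small_city():
    """A compact synthetic city shared by read-only tests."""
    return gen_city(CityConfig(seed=2, grid_n=8))


@pytest.fixture(scope="session")
def small_points(small_city):
    return sampler.sample_points(small_city.network)


@pytest.fixture(scope="session")
def small_summaries(small_city, small_points):
    return render_summaries(small_points, small_city)
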