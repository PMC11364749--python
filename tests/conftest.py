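import numpy as np
import pytest

from mapsort import default_optics, default_populations, simulate_stream


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture(scope="session")
def populations():
    return default_populations()


@pytest.fixture(scope="session")
def small_stream(populations, optics):
    """~600 events of the 3-population demo mixture, fixed seed."""
    events = simulate_stream(populations, event_rate=300.0, duration=2.0, optics=optics, rng_seed=11)
    assert len(events) > 400
    return events


@pytest.fixture(scope="session")
def small_coeffs(small_stream):
    from mapsort.features import coefficient_matrix

    return coefficient_matrix(small_stream)
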