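import numpy as np
import pytest

from linefinder import TimeSeries, worked_example_series


@pytest.fixture
def worked_example() -> TimeSeries:
    """Six-point series with one gross and one mild deviant around
    a = 10x - 40; reference literature values exist for every iteration."""
    return worked_example_series()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20151116)


def make_collinear(n: int, slope: float, intercept: float,
                   x_start: float = 0.0) -> TimeSeries:
    x = x_start + np.arange(n, dtype=float)
    return TimeSeries(x, slope * x + intercept)
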