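import pytest

from glyco import Composition, default_coefficients, load_benchmark, load_benchmark_frame


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture(scope="session")
def milk():
    """Whole milk per 100 g: the classic dilution worked example."""
    return Composition(
        {"water": 88, "lactose": 4.9, "fat": 3.3, "protein": 3.1, "ashes": 0.7}
    )


@pytest.fixture(scope="session")
def benchmark():
    return load_benchmark()


@pytest.fixture(scope="session")
def benchmark_frame():
    return load_benchmark_frame()
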