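import numpy as np
import pytest

from elevdiv import BandScheme, Domain, SpeciesRange


@pytest.fixture
def scheme() -> BandScheme:
    """The standard nine 500-m bands, 500–5000 m."""
    return BandScheme(base=500.0, width=500.0, n_bands=9)


@pytest.fixture
def domain() -> Domain:
    return Domain(500.0, 5000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_ranges(
    rng: np.random.Generator,
    n: int,
    low: float = 500.0,
    high: float = 5000.0,
    integer: bool = False,
) -> list[SpeciesRange]:
    """Random valid species ranges within [low, high]."""
    a = rng.uniform(low, high, size=(n, 2))
    a.sort(axis=1)
    if integer:
        a = np.round(a)
    return [SpeciesRange(f"sp{i}", float(lo), float(hi)) for i, (lo, hi) in enumerate(a)]
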