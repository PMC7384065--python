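import numpy as np
import pytest

from dmriharm import (
    SHBasisSpec,
    ShellTable,
    SiteDataset,
    SiteProfile,
    make_benchmark,
    make_scheme,
)
from dmriharm.sphere import electrostatic_directions


@pytest.fixture(scope="session")
def spec():
    return SHBasisSpec(8)


@pytest.fixture(scope="session")
def table():
    return ShellTable()


@pytest.fixture(scope="session")
def dirs30():
    return electrostatic_directions(30, seed=1)


@pytest.fixture(scope="session")
def dirs60():
    return electrostatic_directions(60, seed=2)


@pytest.fixture(scope="session")
def dirs100():
    return electrostatic_directions(100, seed=3)


@pytest.fixture(scope="session")
def two_site_profiles():
    return [
        SiteProfile("A", make_scheme(30, seed=11), gain=(1.1, 1.1), snr=30.0),
        SiteProfile("B", make_scheme(60, seed=12), gain=(0.9, 0.9), snr=30.0),
    ]


@pytest.fixture(scope="session")
def small_benchmark(two_site_profiles):
    """8^3 two-site benchmark with one training phantom: unit-test scale."""
    return make_benchmark(two_site_profiles, shape=(8, 8, 8), seed=5, n_train=1)


@pytest.fixture(scope="session")
def small_dataset(small_benchmark):
    ds = SiteDataset(["A", "B"])
    for site in ("A", "B"):
        for vol in small_benchmark.train_volumes[site]:
            ds.add_volume(vol, site)
    return ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
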