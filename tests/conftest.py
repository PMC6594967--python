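"""Shared fixtures: a small synthetic world and derived occurrence data.

Session-scoped so the expensive pieces (hex grid, world, records) build
once. Raster resolution is 30 arcmin in tests (the package default is
5 arcmin) purely to keep runtimes down; the statistical structure of the
world is unchanged.
"""

import numpy as np
import pytest

import hexdiv
from hexdiv.synthetic import GeneratorParams, generate_world, sample_occurrences

TEST_ARCMIN = 30.0


@pytest.fixture(scope="session")
def grid():
    return hexdiv.build_hex_grid()


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(n_species=2000, raster_arcmin=TEST_ARCMIN, seed=11)


@pytest.fixture(scope="session")
def small_world(small_params):
    return generate_world(small_params)


@pytest.fixture(scope="session")
def small_records(small_world):
    return sample_occurrences(small_world, 12_000, seed=12)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results independent of test order
    return np.random.default_rng(7)
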