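"""Shared fixtures: phantom cases at two sizes and the default source."""

import numpy as np
import pytest

import brachyrobust as br


@pytest.fixture(scope="session")
def source():
    return br.synthetic_ir192()


@pytest.fixture(scope="session")
def small_spec():
    # a reduced gland keeps unit tests fast while exercising every code path
    return br.PhantomSpec(prostate_volume_cc=15.0, n_needles=8)


@pytest.fixture(scope="session")
def small_case(small_spec, source):
    return br.normalize_dwell_times(br.generate_phantom(small_spec), source,
                                    grid_spacing=2.0)


@pytest.fixture(scope="session")
def small_paths(small_case):
    return br.build_needle_paths(small_case.dwells)


@pytest.fixture(scope="session")
def default_case(source):
    """The study-sized phantom: ≈38 cc prostate, 16 needles, D90 = 16 Gy."""
    return br.normalize_dwell_times(br.generate_phantom(), source)


@pytest.fixture(scope="session")
def default_paths(default_case):
    return br.build_needle_paths(default_case.dwells)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
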