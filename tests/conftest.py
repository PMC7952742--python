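"""Shared fixtures: sequences, profiles, a reduced dictionary and a noisy
phantom reused across test modules (session scope keeps the suite fast)."""

import numpy as np
import pytest

from wt2map import (
    PhantomSpec,
    SequenceParams,
    build_dictionary,
    build_grid,
    default_profile,
    make_phantom,
    rectangular_profile,
)

REDUCED_GRID_KW = dict(wt2_steps=15, b1_steps=10, ff_steps=26)


@pytest.fixture(scope="session")
def seq17() -> SequenceParams:
    return SequenceParams()


@pytest.fixture(scope="session")
def rect_profile():
    return rectangular_profile()


@pytest.fixture(scope="session")
def sinc_profile(seq17):
    return default_profile(seq17)


@pytest.fixture(scope="session")
def reduced_grid():
    return build_grid(**REDUCED_GRID_KW)


@pytest.fixture(scope="session")
def reduced_dictionary(reduced_grid, seq17, sinc_profile):
    """15 x 10 x 26 dictionary with the default slice profile, 17 echoes."""
    return build_dictionary(reduced_grid, seq17, sinc_profile)


@pytest.fixture(scope="session")
def phantom42(seq17, sinc_profile):
    """Default digital phantom: seed 42, SNR 50, B1 gradient 0.8-1.2."""
    return make_phantom(PhantomSpec(seed=42), seq17, sinc_profile)


@pytest.fixture(scope="session")
def noiseless_phantom(seq17, rect_profile):
    """Small ideal phantom: no noise, constant B1 = 1, hard pulses."""
    spec = PhantomSpec(
        shape=(1, 32, 32), noise_sigma=0.0, snr=None,
        b1_field="constant", b1_range=(1.0, 1.0), seed=7,
    )
    return make_phantom(spec, seq17, rect_profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
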