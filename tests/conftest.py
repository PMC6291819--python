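"""Shared fixtures: phantoms are generated once per session and reused."""

from dataclasses import replace

import numpy as np
import pytest

from octguide.evaluation import study_phantom_spec
from octguide.phantom import (
    NoiseSpec,
    PhantomSpec,
    make_cbct_phantom,
    make_oct_volume,
)

NOISE_FREE = NoiseSpec(cbct_gaussian_sd=0.0, oct_speckle_scale=0.0)


@pytest.fixture(scope="session")
def spec_clean() -> PhantomSpec:
    """Default phantom geometry with all imaging noise disabled."""
    return replace(PhantomSpec(seed=1), noise=NOISE_FREE)


@pytest.fixture(scope="session")
def phantom_clean(spec_clean):
    return make_cbct_phantom(spec_clean)


@pytest.fixture(scope="session")
def oct_clean(spec_clean, phantom_clean):
    _, truth = phantom_clean
    return make_oct_volume(spec_clean, truth)


@pytest.fixture(scope="session")
def spec_noisy() -> PhantomSpec:
    """Default phantom with default (realistic) noise levels."""
    return PhantomSpec(seed=2)


@pytest.fixture(scope="session")
def phantom_noisy(spec_noisy):
    return make_cbct_phantom(spec_noisy)


@pytest.fixture(scope="session")
def spec_study_noisy() -> PhantomSpec:
    """Study-scale phantom (coarse lateral OCT pitch), default noise."""
    return study_phantom_spec(seed=3)


@pytest.fixture(scope="session")
def phantom_study_noisy(spec_study_noisy):
    return make_cbct_phantom(spec_study_noisy)


@pytest.fixture(scope="session")
def oct_study_noisy(spec_study_noisy, phantom_study_noisy):
    _, truth = phantom_study_noisy
    return make_oct_volume(spec_study_noisy, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
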