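import dataclasses

import numpy as np
import pytest

from fibroquant import CohortSpec, SectionSpec, default_color_model


@pytest.fixture(scope="session")
def color_model():
    return default_color_model()


@pytest.fixture
def small_section_spec():
    return SectionSpec(
        width_px=160,
        height_px=160,
        true_collagen_fraction=0.12,
        true_elastin_fraction=0.04,
        true_nucleus_fraction=0.08,
        color_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def big_fiber_sample():
    """One shared n=100k draw from the default fiber model."""
    from fibroquant import sample_fibers

    spec = CohortSpec(n=100_000, seed=5)
    return sample_fibers(spec)


def vary(spec, **kw):
    return dataclasses.replace(spec, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
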