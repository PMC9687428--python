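import dataclasses

import numpy as np
import pytest

from renalseg import PhantomConfig, build_pb_prior, make_population
from renalseg.phantom import draw_geometry, make_subject


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_config():
    """Fast 64x64, 8-frame phantom used by unit tests."""
    return PhantomConfig(
        image_size=(64, 64),
        n_frames=8,
        geometry=dataclasses.replace(PhantomConfig().geometry, center=(32.0, 32.0),
                                     a=16.0, b=9.0),
        center_sd=2.0,
        axis_sd=1.2,
        orientation_sd=5.0,
        breathing_translation=1.0,
        breathing_rotation=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pb_prior(small_phantom_config):
    """PB prior from 6 small synthetic subjects, no registration (already posed)."""
    pop = make_population(6, dataclasses.replace(small_phantom_config, seed=500))
    return build_pb_prior([p.frame for p in pop], [p.mask for p in pop],
                          beta=1.0, register=False)


# ---- study-scale fixtures shared by the acceptance tests (expensive) ----

ACCEPT_PHANTOM = PhantomConfig(n_frames=20, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def accept_pb_prior():
    """PB prior from 10 synthetic subjects at 128x128 (registered training)."""
    pop = make_population(10, PhantomConfig(n_frames=20, seed=100))
    return build_pb_prior([p.frame for p in pop], [p.mask for p in pop], beta=1.0)


@pytest.fixture(scope="session")
def accept_subject():
    """Noise-free 20-frame test subject with geometry drawn from the population."""
    geom = draw_geometry(ACCEPT_PHANTOM, 7000)
    return make_subject(ACCEPT_PHANTOM, geometry=geom)


@pytest.fixture(scope="session")
def accept_subject_noisy():
    """Same subject corrupted by sigma=0.01 Gaussian noise on [0,1] intensities."""
    geom = draw_geometry(ACCEPT_PHANTOM, 7000)
    return make_subject(dataclasses.replace(ACCEPT_PHANTOM, noise_sigma=0.01),
                        geometry=geom)
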