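import dataclasses

import numpy as np
import pytest

from aimtk.phantom import CellClass, NoiseModel, PhantomSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_spec():
    """Large, well-separated cells with big nuclei: the 'easy' staining task."""
    return PhantomSpec(
        image_size=(128, 128),
        n_cells=3,
        cell_radius_range=(16.0, 22.0),
        nucleus_radius_fraction=0.5,
        seed=5,
    )


@pytest.fixture(scope="session")
def two_class_spec():
    """Two separable morphology classes: round vs elongated."""
    classes = [
        CellClass("round", (0.0, 0.25), 0.15, 1.0),
        CellClass("elongated", (0.85, 0.95), 0.35, 0.8),
    ]
    return PhantomSpec(
        image_size=(192, 192),
        n_cells=5,
        cell_radius_range=(12.0, 16.0),
        class_defs=classes,
        seed=3,
    )


def sample_specs(base: PhantomSpec, ids, seed0=50):
    return [
        dataclasses.replace(base, sample_id=str(s), seed=seed0 + i)
        for i, s in enumerate(ids)
    ]


@pytest.fixture(scope="session")
def noisy():
    return NoiseModel(gaussian_sigma=0.02, poisson_scale=200.0)
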