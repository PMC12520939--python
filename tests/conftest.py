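import numpy as np
import pytest

from hsrpi.spectral_library import default_axis, default_library
from hsrpi.synthetic_data import (
    CohortConfig,
    LEUKEMIA_CLASSES,
    generate_cohort,
    load_default_profiles,
)


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def library(axis):
    return default_library(axis)


@pytest.fixture(scope="session")
def small_cohort(library, tmp_path_factory):
    """Six leukemia classes x 4 cells, default noise; shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(
        classes=load_default_profiles(LEUKEMIA_CLASSES),
        cells_per_class=4,
        image_size=(160, 160),
        cells_per_field=8,
        seed=123,
    )
    manifest = generate_cohort(cfg, out, library)
    return out, manifest, cfg


def three_class_fixture(rng, n_per_class=30, sep=6.0):
    """Linearly separable 3-class Gaussian table in 5 features."""
    means = {
        "alpha": np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
        "beta": np.array([sep, 0.0, sep / 2, 0.0, 0.0]),
        "gamma": np.array([0.0, sep, 0.0, sep / 2, 0.0]),
    }
    X, labels = [], []
    for name, mu in means.items():
        X.append(rng.normal(mu, 1.0, size=(n_per_class, 5)))
        labels += [name] * n_per_class
    return np.vstack(X), labels, means
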