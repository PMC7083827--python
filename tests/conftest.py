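import numpy as np
import pytest

from tarsomorph import (
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    default_tarsus_scheme,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tarsus_scheme():
    return default_tarsus_scheme()


@pytest.fixture
def quad_scheme():
    """A minimal 4-point scheme without semilandmarks for toy shapes."""
    return LandmarkScheme(n_landmarks=4)


def make_dataset(coords_by_id, scheme, label="other"):
    configs = [
        LandmarkConfiguration(specimen_id=sid, coords=np.asarray(c, float), side="left")
        for sid, c in coords_by_id.items()
    ]
    return LandmarkDataset(scheme=scheme, configurations=configs, configuration_label=label)


@pytest.fixture
def quad_dataset(quad_scheme, rng):
    """Three generic 4-point shapes (no symmetry, no coincident points)."""
    base = np.array([[0.0, 0.0], [3.0, 0.4], [2.6, 2.0], [0.5, 1.7]])
    shapes = {
        f"s{i}": base + 0.25 * rng.normal(size=base.shape) for i in range(3)
    }
    return make_dataset(shapes, quad_scheme)
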