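import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bootseg.synth import SynthParams, generate_labels
from bootseg.volumes import LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labels(rng) -> LabelVolume:
    """Random dense 16^3 labels with a handful of ids, 10 nm isotropic."""
    data = rng.integers(0, 5, size=(16, 16, 16)).astype(np.uint64)
    return LabelVolume(data, voxel_size=(10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def synthetic_volume() -> LabelVolume:
    """One 48^3 space-filling synthetic volume shared across tests."""
    return generate_labels(SynthParams(shape=(48, 48, 48), num_objects=(12, 18),
                                       voxel_size=(40.0, 8.0, 8.0), seed=7))
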