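import dataclasses

import numpy as np
import pytest

from mshts.simulate import SimulationParams


@pytest.fixture
def small_params() -> SimulationParams:
    """Reduced-size rendering parameters for fast unit tests; density is kept
    per-area so texture statistics resemble the full frame."""
    return dataclasses.replace(
        SimulationParams(),
        image_size=(128, 128),
        filament_scale=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
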