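import dataclasses

import numpy as np
import pytest

from darcamd.synthdata import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast cohort: 8 eyes, 128-px images, 25-slice volumes."""
    return CohortConfig(
        n_eyes=8, image_size=(128, 128), slices_per_volume=25,
        mask_depth=32, lesion_semiaxis_min=6.0, lesion_semiaxis_max=14.0,
        seed=7,
    )


def tiny(config: CohortConfig = None, **overrides) -> CohortConfig:
    base = config or CohortConfig(
        n_eyes=8, image_size=(128, 128), slices_per_volume=25,
        mask_depth=32, lesion_semiaxis_min=6.0, lesion_semiaxis_max=14.0,
        seed=7,
    )
    return dataclasses.replace(base, **overrides) if overrides else base
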