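import numpy as np
import pytest

from histomil import CohortSpec, DatasetSpec, StainCast, TextureParams


@pytest.fixture(scope="session")
def small_spec():
    """A tiny balanced single-dataset cohort spec with 512x512 slides."""
    return CohortSpec(
        datasets=(DatasetSpec("D1", 3, 3),),
        slide_size=(512, 512),
        tissue_fraction=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
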