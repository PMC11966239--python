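import numpy as np
import pytest

import cryofield as cf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """8-pixel box at 1 A with 4 depth samples."""
    return cf.build_grid(8, 1.0, 4)


@pytest.fixture
def tiny_hash_field():
    """A small hash-grid field with non-trivial table values."""
    cfg = cf.HashGridConfig(
        L=2, F=2, log2_hashmap_size=8, base_resolution=3,
        finest_resolution=5, mlp_hidden=8,
    )
    field = cf.HashGridField(8.0, cfg, seed=0)
    r = np.random.default_rng(7)
    for name in field.table_names:
        field.params[name] += r.normal(0, 0.2, field.params[name].shape)
    return field


@pytest.fixture
def bead_phantom():
    """Compact 12-bead model in a 24 A box."""
    return cf.random_bead_model(12, 24.0, seed=3, amplitude=1.0, width=2.0)
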