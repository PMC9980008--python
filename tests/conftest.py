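import numpy as np
import pytest

import ngffkit as nk


@pytest.fixture()
def image_store(tmp_path):
    """Pristine two-level spots image with an attached label image."""
    root = tmp_path / "img"
    nk.synth_image_store(root)
    return root


@pytest.fixture()
def plate_store(tmp_path):
    """Pristine 2x2 plate, one gradient field per well."""
    root = tmp_path / "plate"
    nk.synth_plate(root, 2, 2, 1, nk.SceneSpec(shape=(1, 1, 1, 32, 32)), seed=3)
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
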