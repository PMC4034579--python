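import numpy as np
import pytest

from salicsd import natural_image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def leaves_img():
    """One dead-leaves scene at the sparse branch's working resolution."""
    return natural_image(60, 80, seed=7)


@pytest.fixture()
def png_path(tmp_path):
    """Write an 8-bit RGB test image to disk and return its path."""
    from PIL import Image

    arr = (np.linspace(0, 1, 12 * 10 * 3).reshape(12, 10, 3) * 255).astype(np.uint8)
    path = tmp_path / "img.png"
    Image.fromarray(arr).save(path)
    return path
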