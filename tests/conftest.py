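import numpy as np
import pytest
from PIL import Image

from stimpat.stimuli import LuminanceImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def png_factory(tmp_path):
    """Write an array (2D grayscale in [0,1] or HxWx3 uint8 RGB) as a PNG."""

    def _write(arr, name="img.png"):
        arr = np.asarray(arr)
        if arr.ndim == 2:
            pil = Image.fromarray(
                np.clip(arr * 255.0, 0, 255).astype(np.uint8), mode="L")
        else:
            pil = Image.fromarray(arr.astype(np.uint8), mode="RGB")
        path = tmp_path / name
        pil.save(path)
        return path

    return _write


@pytest.fixture
def random_images(rng):
    """Four random 16x16 luminance images."""
    return [LuminanceImage(rng.random((16, 16))) for _ in range(4)]
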