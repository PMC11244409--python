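import numpy as np
import pytest

from ecgnpu.fp16 import floats_to_image, image_to_floats


def quantize(a):
    """Snap an array to exact binary16 values (as float64)."""
    return image_to_floats(floats_to_image(np.asarray(a, dtype=float)))


def random_layer(rng, max_ch=32, max_kernel=12, max_out_len=24):
    """A random quantised conv layer: (input, weights, stride)."""
    c_in = int(rng.integers(1, max_ch + 1))
    c_out = int(rng.integers(1, max_ch + 1))
    k = int(rng.integers(1, max_kernel + 1))
    stride = int(rng.integers(1, 4))
    out_len = int(rng.integers(1, max_out_len + 1))
    in_len = (out_len - 1) * stride + k
    x = quantize(rng.normal(scale=1.0, size=(c_in, in_len)))
    w = quantize(rng.normal(scale=0.3, size=(c_out, c_in, k)))
    return x, w, stride


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
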