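import numpy as np
import pytest
from scipy import ndimage

import vistrf


@pytest.fixture(scope="session")
def small_session():
    """A small high-SNR synthetic session shared by read-only tests."""
    cfg = vistrf.SimConfig(n_trials=4, duration=15.0, n_channels=8,
                           snr_db=10.0, seed=7)
    return vistrf.simulate_session(cfg)


@pytest.fixture
def smooth_texture():
    """Factory for smooth random frames: the regime where block matching by
    greedy descent finds the global optimum."""

    def make(rng, shape=(96, 96), sigma=3.0):
        return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)

    return make


def shifted_pair(rng, make_texture, shift, margin=16, size=64):
    """A (ref, target) frame pair where target content is ref translated by
    ``shift``, built by cropping a larger texture so borders stay genuine."""
    sy, sx = shift
    big = make_texture(rng, (size + 2 * margin, size + 2 * margin))
    moved = np.roll(np.roll(big, sy, axis=0), sx, axis=1)
    sl = slice(margin, margin + size)
    return big[sl, sl], moved[sl, sl]


def feasible_blocks(shape, block_size, shift):
    """Mask of blocks whose true displacement keeps the match window in-frame."""
    sy, sx = shift
    n_by, n_bx = shape[0] // block_size, shape[1] // block_size
    mask = np.zeros((n_by, n_bx), dtype=bool)
    for by in range(n_by):
        for bx in range(n_bx):
            y0, x0 = by * block_size, bx * block_size
            mask[by, bx] = (
                0 <= y0 + sy <= shape[0] - block_size
                and 0 <= x0 + sx <= shape[1] - block_size
            )
    return mask
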