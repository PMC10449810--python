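import numpy as np
import pytest

from emphymap.imaging_io import BinaryMask, SlicePattern, Window2D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_window():
    """60x60 mm all-lung window on a 1 mm grid."""
    return Window2D(np.ones((60, 60), dtype=bool), (1.0, 1.0))


def random_lung_laa(rng, shape, lung_p=0.8, laa_p=0.35):
    """A random lung mask and a random LAA subset of it."""
    lung = rng.random(shape) < lung_p
    laa = lung & (rng.random(shape) < laa_p)
    return (
        BinaryMask(laa, spacing=(1.0, 1.0, 1.0), role="LAA"),
        BinaryMask(lung, spacing=(1.0, 1.0, 1.0), role="lung"),
    )


def four_cluster_pattern(seed, window, k=4, w=150.0, sigma=3.0, noise_share=0.15):
    """Well-separated truth pattern used for parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    lo, hi = 15.0, 45.0
    centers = np.array([[lo, lo], [lo, hi], [hi, lo], [hi, hi]])[:k]
    pts = []
    for c in centers:
        draw = rng.multivariate_normal(c, sigma**2 * np.eye(2), rng.poisson(w))
        pts.append(draw[window.contains(draw)])
    n_noise = rng.poisson(k * w * noise_share / (1.0 - noise_share))
    extent = np.array(window.grid.shape) * np.array(window.spacing)
    pts.append(rng.random((n_noise, 2)) * extent)
    return SlicePattern(np.vstack(pts), window)
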