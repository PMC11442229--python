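"""Shared fixtures: small synthetic crosses and the normalized shape templates."""

import numpy as np
import pytest

from cranqtl.simulate import simulate_cross, simulate_map
from cranqtl.templates import shape_templates


@pytest.fixture(scope="session")
def small_map():
    """Three 100-cM linkage groups with 11 evenly spaced markers each."""
    return simulate_map(3, 11, 100.0, seed=101)


@pytest.fixture(scope="session")
def small_cross(small_map):
    return simulate_cross(small_map, 120, seed=102)


@pytest.fixture(scope="session")
def templates():
    """The five normalized berry-shape class templates (256x256, area 12000)."""
    return shape_templates()


def random_blob(rng, size=24, n_seeds=3, dilations=3):
    """A random connected binary blob for shape-pipeline fixtures."""
    from scipy import ndimage

    img = np.zeros((size, size), dtype=bool)
    ys = rng.integers(size // 4, 3 * size // 4, n_seeds)
    xs = rng.integers(size // 4, 3 * size // 4, n_seeds)
    img[ys, xs] = True
    for _ in range(dilations):
        img = ndimage.binary_dilation(img)
    lab, n = ndimage.label(img)
    if n > 1:
        sizes = ndimage.sum_labels(img, lab, index=np.arange(1, n + 1))
        img = lab == (int(np.argmax(sizes)) + 1)
    return img.astype(np.uint8)
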