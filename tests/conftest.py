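import numpy as np
import pytest

from consenseg.io import LabelMask, connected_components


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(64, 64), n_blobs=5, radius=(3, 6)) -> LabelMask:
    """Disjoint random disks, component-labeled."""
    H, W = shape
    canvas = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    placed = 0
    for _ in range(200):
        if placed == n_blobs:
            break
        r = rng.uniform(*radius)
        cy, cx = rng.uniform(r + 1, H - r - 1), rng.uniform(r + 1, W - r - 1)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        # keep blobs separated so each disk is one object
        grown = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 2) ** 2
        if not (canvas & grown).any():
            canvas |= blob
            placed += 1
    return connected_components(canvas)
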