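import numpy as np
import pytest

from tilewalk import BinaryMask, DistanceMap


@pytest.fixture
def single_voxel_mask():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[1, 1, 1] = True
    return BinaryMask(m)


@pytest.fixture
def bar_1x1x5_map():
    """All-foreground 1x1x5 line with values [1,3,2,4,1] (axis adjacency)."""
    vals = np.array([[[1.0, 3.0, 2.0, 4.0, 1.0]]])
    mask = BinaryMask(np.ones((1, 1, 5), dtype=bool))
    return DistanceMap(vals, mask)
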