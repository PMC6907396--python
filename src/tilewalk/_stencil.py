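"""Neighbor stencils on the voxel grid.

Connectivity follows the usual 3D convention: 6 = faces, 18 = faces+edges,
26 = full cube.  Offsets are returned as an (n, 3) int array of (dz, dy, dx).
"""

from __future__ import annotations

import numpy as np

_VALID = (6, 18, 26)


def stencil_offsets(connectivity: int) -> np.ndarray:
    if connectivity not in _VALID:
        raise ValueError(f"connectivity must be one of {_VALID}, got {connectivity}")
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


def scipy_structure(connectivity: int) -> np.ndarray:
    """The 3x3x3 structuring element equivalent, for scipy.ndimage."""
    st = np.zeros((3, 3, 3), dtype=bool)
    st[1, 1, 1] = True
    for dz, dy, dx in stencil_offsets(connectivity):
        st[1 + dz, 1 + dy, 1 + dx] = True
    return st
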