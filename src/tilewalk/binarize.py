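"""Foreground extraction: global thresholding and small-component removal."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._stencil import scipy_structure
from .grids import BinaryMask, IntensityVolume, LabelVolume


def threshold_mask(
    volume: IntensityVolume, threshold: float, invert: bool = False
) -> BinaryMask:
    """Global threshold: foreground is intensity >= ``threshold``.

    Mineralized tissue is bright in microCT, hence the bright-foreground
    convention; pass ``invert`` for dark-foreground data (< threshold).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    fg = volume.data < threshold if invert else volume.data >= threshold
    return BinaryMask(fg, volume.spacing)


def remove_small_components(
    mask_or_labels: BinaryMask | LabelVolume,
    min_voxels: int,
    connectivity: int = 26,
) -> BinaryMask | LabelVolume:
    """Drop tiny objects: components (masks) or labels under ``min_voxels``.

    For a :class:`BinaryMask`, connected components (at the given stencil
    connectivity) smaller than ``min_voxels`` become background.  For a
    :class:`LabelVolume`, labels with a total voxel count under the cutoff
    become background; connectivity is ignored since label identity already
    defines the objects.  Idempotent.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if isinstance(mask_or_labels, BinaryMask):
        mask = mask_or_labels
        structure = scipy_structure(connectivity)
        comp, n = ndimage.label(mask.data, structure=structure)
        if n == 0:
            return BinaryMask(mask.data.copy(), mask.spacing)
        counts = np.bincount(comp.ravel(), minlength=n + 1)
        keep = counts >= min_voxels
        keep[0] = False
        return BinaryMask(keep[comp], mask.spacing)
    labels = mask_or_labels
    max_label = int(labels.data.max()) if labels.data.size else 0
    counts = np.bincount(labels.data.ravel(), minlength=max_label + 1)
    lut = np.arange(max_label + 1, dtype=labels.data.dtype)
    lut[counts < min_voxels] = 0
    lut[0] = 0
    return LabelVolume(lut[labels.data], labels.spacing)
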