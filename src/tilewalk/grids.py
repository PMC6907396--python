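"""Core in-memory containers shared by the whole toolkit.

All grids use a fixed ``(z, y, x)`` axis order: ``z`` is the slice axis of
the acquisition stack, voxel ``(0, 0, 0)`` is the first pixel of the first
slice, and coordinates are 0-based.  ``spacing`` is the physical size of a
voxel along each axis, in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)  # type: ignore[assignment]
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {spacing!r}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing components must be finite and positive, got {spacing!r}")
    return spacing


def _check_3d(data: np.ndarray, name: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"{name} must be 3D (z, y, x), got shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"{name} has an empty axis: shape {data.shape}")
    return data


@dataclass
class IntensityVolume:
    """A 3D scalar image (raw or filtered), axis order (z, y, x)."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "IntensityVolume.data")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A 3D boolean grid; True marks the structures of interest (foreground)."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "BinaryMask.data").astype(bool, copy=False)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class DistanceMap:
    """A distance-like scalar field defined on a mask's foreground.

    Values are 0 on background and strictly positive on foreground.  Units
    are walk steps for the random-walk transform and physical length (or
    voxels) for the Euclidean transform.
    """

    data: np.ndarray
    mask: BinaryMask

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "DistanceMap.data").astype(np.float64, copy=False)
        if self.data.shape != self.mask.shape:
            raise ValueError(
                f"distance data shape {self.data.shape} != mask shape {self.mask.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("distance map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> Spacing:
        return self.mask.spacing

    def foreground_values(self) -> np.ndarray:
        return self.data[self.mask.data]


@dataclass
class LabelVolume:
    """A 3D integer grid of object identities; 0 is background."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "LabelVolume.data")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted array of the nonzero labels present."""
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels().size)


@dataclass
class PhantomBundle:
    """A synthetic volume with known ground truth.

    ``truth`` holds the ideal (pre-carving) tile identities, so the mask
    satisfies ``mask.data <= (truth.data > 0)`` with equality when no
    constrictions were carved; every mask voxel has exactly one truth label.
    ``params`` records the full generation parameter set including the seed,
    which reproduces the bundle bit-exactly.
    """

    image: IntensityVolume
    truth: LabelVolume
    mask: BinaryMask
    params: dict = field(default_factory=dict)
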