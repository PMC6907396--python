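"""Volume, mask, and label I/O with spacing metadata.

Supported containers: multipage grayscale TIFF, a directory of equally
shaped 2D TIFF/PNG slices (z order = natural-number order of the file
names), and NRRD.  The in-memory axis order is always (z, y, x); NRRD
spacing, which SimpleITK reports as (x, y, z), is reversed on the way in
and out.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .grids import BinaryMask, IntensityVolume, LabelVolume, Spacing

log = logging.getLogger(__name__)

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def natural_sort_key(name: str) -> tuple:
    """Split digit runs out of a string so 's10' sorts after 's2'."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) slice -> first channel
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"slice {path} is not 2D (shape {arr.shape})")
    return arr


def _read_array(path: Path) -> tuple[np.ndarray, Spacing | None]:
    """Return (zyx array, spacing or None if the format carries none)."""
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES),
            key=lambda p: natural_sort_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices found in directory {path}")
        slices = [_read_slice(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        return np.stack(slices, axis=0), None
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path} is not a 3D grayscale stack (shape {arr.shape})")
        return arr, None
    if suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if arr.ndim != 3:
            raise ValueError(f"{path} is not a 3D NRRD (shape {arr.shape})")
        spacing_xyz = img.GetSpacing()
        return arr, tuple(reversed(spacing_xyz))  # type: ignore[return-value]
    raise ValueError(f"unsupported volume format: {path}")


def _resolve_spacing(
    from_file: Spacing | None, override: Spacing | None, path: Path
) -> Spacing:
    if override is not None:
        spacing = tuple(float(s) for s in override)
    elif from_file is not None:
        spacing = tuple(float(s) for s in from_file)
    else:
        log.warning("no spacing metadata for %s; assuming isotropic 1.0", path)
        spacing = (1.0, 1.0, 1.0)
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing} for {path}")
    return spacing  # type: ignore[return-value]


def read_volume(path, spacing_override: Spacing | None = None) -> IntensityVolume:
    """Read a 3D grayscale volume as an :class:`IntensityVolume`.

    ``path`` may be a multipage TIFF, an NRRD file, or a directory of
    equally shaped 2D TIFF/PNG slices whose natural-number name order
    defines the z order.  ``spacing_override`` takes precedence over any
    metadata; without either, spacing defaults to (1, 1, 1) with a warning.
    """
    path = Path(path)
    arr, spacing = _read_array(path)
    return IntensityVolume(arr, _resolve_spacing(spacing, spacing_override, path))


def read_mask(path, spacing_override: Spacing | None = None, threshold: float = 0.5) -> BinaryMask:
    """Read a binary mask: nonzero (> ``threshold``) voxels are foreground."""
    vol = read_volume(path, spacing_override)
    return BinaryMask(vol.data > threshold, vol.spacing)


def read_labels(path, spacing_override: Spacing | None = None) -> LabelVolume:
    """Read an integer label volume."""
    path = Path(path)
    arr, spacing = _read_array(path)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            raise ValueError(f"{path} holds non-integer values; not a label volume")
        arr = rounded.astype(np.int64)
    return LabelVolume(arr, _resolve_spacing(spacing, spacing_override, path))


def _write_array(arr: np.ndarray, path: Path, spacing: Spacing) -> None:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr, photometric="minisblack")
    elif suffix == ".nrrd":
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(reversed(spacing)))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported output format: {path}")


def write_volume(volume: IntensityVolume | DistanceMapLike, path) -> None:
    """Write an intensity (or distance) volume as TIFF or NRRD."""
    path = Path(path)
    data = volume.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # distance maps as 32-bit float
    _write_array(data, path, volume.spacing)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit volume (foreground = 255)."""
    path = Path(path)
    _write_array((mask.data.astype(np.uint8) * 255), path, mask.spacing)


def write_labels(labels: LabelVolume, path) -> None:
    """Write a label volume as unsigned-integer TIFF/NRRD.

    Uses 16-bit when the maximum label fits below 65536, else 32-bit; the
    file re-reads to a bit-identical grid.
    """
    path = Path(path)
    max_label = int(labels.data.max()) if labels.data.size else 0
    if max_label >= 2**32:
        raise ValueError(f"label {max_label} exceeds 32-bit range")
    dtype = np.uint16 if max_label < 2**16 else np.uint32
    _write_array(labels.data.astype(dtype), path, labels.spacing)


class DistanceMapLike:  # typing helper only: anything with .data and .spacing
    data: np.ndarray
    spacing: Spacing
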