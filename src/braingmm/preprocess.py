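"""Grayscale conversion, linear intensity normalization and median filtering.

Images are plain 2-D float arrays in gray-level units; the package works on
[0, 255] floats throughout and quantizes to 8-bit only at file export.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "to_grayscale",
    "normalize_linear",
    "median_filter",
    "read_image",
    "write_image",
    "read_dicom_slice",
    "read_nifti_slice",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image) -> np.ndarray:
    """Reduce a 1- or 3-channel raster to a single gray channel (BT.601)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].copy()
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ _LUMA
    raise ValueError(f"unsupported channel layout: shape {arr.shape}")


def normalize_linear(image, out_range=(0.0, 255.0)) -> np.ndarray:
    """Affinely map [min, max] onto out_range; constant images map to the low end."""
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    lo, hi = float(out_range[0]), float(out_range[1])
    amin, amax = float(arr.min()), float(arr.max())
    if amax == amin:
        return np.full_like(arr, lo)
    return (arr - amin) / (amax - amin) * (hi - lo) + lo


def median_filter(image, window: int = 3) -> np.ndarray:
    """Square median filter with reflect border padding; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    arr = np.asarray(image, dtype=float)
    return ndimage.median_filter(arr, size=window, mode="reflect")


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF (or any imageio-supported raster) as grayscale floats."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    return to_grayscale(arr)


def write_image(path, image, *, binary: bool = False) -> None:
    """Write a gray image (or mask) as 8-bit PNG; masks become 0/255."""
    import imageio.v3 as iio

    arr = np.asarray(image)
    if binary or arr.dtype == bool:
        out = np.where(arr.astype(bool), 255, 0).astype(np.uint8)
    else:
        out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_dicom_slice(path) -> np.ndarray:
    """Read a single DICOM slice as grayscale floats (requires pydicom)."""
    import pydicom

    ds = pydicom.dcmread(Path(path))
    return np.asarray(ds.pixel_array, dtype=float)


def read_nifti_slice(path, index: int = 0, axis: int = 2) -> np.ndarray:
    """Read one 2-D slice from a NIfTI volume (requires nibabel)."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 2:
        return vol
    return np.take(vol, index, axis=axis)
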