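"""Reading and writing 2D grayscale images.

All pipeline stages operate on float64 arrays in [0, 1], index order
(y, x), 0-based.  PNG/TIFF images (8- or 16-bit) are rescaled by their
dtype range on load; single-slice NIfTI files are min-max scaled.
"""

from __future__ import annotations

import os

import numpy as np


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check the GrayImage contract: 2D, finite, in [0,1], at least 8x8."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale array, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image too small: {arr.shape} (need at least 8x8)")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
        raise ValueError("image values must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1]."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nii", ".gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim == 3:
            data = data[:, :, data.shape[2] // 2]
        lo, hi = float(data.min()), float(data.max())
        arr = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
        return validate_image(arr)

    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3:  # RGB(A): average color channels
        raw = raw[..., :3].mean(axis=-1)
    if np.issubdtype(raw.dtype, np.integer):
        arr = raw.astype(float) / float(np.iinfo(raw.dtype).max)
    else:
        arr = raw.astype(float)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    return validate_image(arr)


def save_image(path: str, pixels: np.ndarray) -> None:
    """Write a [0,1] float array as an 8-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def save_mask(path: str, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path: str) -> np.ndarray:
    """Load a binary mask (any nonzero pixel counts as foreground)."""
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., :3].max(axis=-1)
    return raw > (raw.max() / 2 if raw.max() > 1 else 0.5)


def mirror_pad(image: np.ndarray, pad: int) -> np.ndarray:
    """Mirror-extend an image on all sides (for periodic-FFT filtering)."""
    return np.pad(image, pad, mode="reflect")
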