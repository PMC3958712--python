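"""Image and configuration I/O.

Images are loaded as single-channel float64 arrays normalised to [0,1]:
integer dtypes are divided by their dtype maximum; float inputs outside
[0,1] are min-max rescaled.  RGB(A) inputs are reduced to luminance.
Masks are written as 8-bit {0,255} PNG; float fields round-trip through
NPY.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .params import ModelParams

__all__ = ["load_image", "save_image", "save_mask", "save_field", "load_params"]

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0.0 or hi > 1.0:
            arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def save_image(path, image) -> None:
    """Write a [0,1] float field as 8-bit grayscale (or raw NPY)."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() == ".npy":
        np.save(path, image)
        return
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8))


def save_mask(path, mask) -> None:
    """Write a {0,1} mask as {0,255} 8-bit PNG (or raw NPY)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix.lower() == ".npy":
        np.save(path, mask.astype(np.uint8))
        return
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def save_field(path, field) -> None:
    """Write a float field (e.g. phi) as NPY."""
    np.save(Path(path), np.asarray(field, dtype=np.float64))


def load_params(path) -> ModelParams:
    """Read a flat YAML/JSON key-value config into :class:`ModelParams`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ModelParams()
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return ModelParams.from_mapping(data)
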