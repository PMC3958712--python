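"""Ground-truthed synthetic phantoms and segmentation quality metrics.

The generator emulates the regime the segmentation model targets:
piecewise-constant two-region scenes corrupted by a smooth multiplicative
bias field (intensity inhomogeneity, as produced by uneven illumination or
MRI coil shading) and additive Gaussian noise, with geometries ranging
from a disk to thin branching vessel trees whose boundaries are weak.
Every phantom is fully determined by its arguments and seed.

    image = clip(base * bias_field + noise, 0, 1)
    base  = fg_level on the truth mask, bg_level elsewhere
    bias_field = 1 + bias_amplitude * pattern,  pattern normalised to [-1,1]

The pattern is seed-selected between a low-order polynomial and a single
low-frequency sinusoid, both smooth and slowly varying across the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Phantom", "make_phantom", "dice", "jaccard", "SHAPES", "bias_blob_128", "FIXTURES"]

SHAPES = ("disk", "T_shape", "vessel_tree", "blob")


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    truth_mask: np.ndarray
    bias_field: np.ndarray
    noise_sigma: float
    seed: int


def _disk_mask(H: int, W: int) -> np.ndarray:
    ci, cj = (H - 1) / 2.0, (W - 1) / 2.0
    r = 0.3 * min(H, W)
    ii, jj = np.indices((H, W))
    return (ii - ci) ** 2 + (jj - cj) ** 2 <= r**2


def _t_mask(H: int, W: int) -> np.ndarray:
    mask = np.zeros((H, W), dtype=bool)
    mask[int(0.15 * H) : int(0.35 * H), int(0.20 * W) : int(0.80 * W)] = True  # bar
    mask[int(0.35 * H) : int(0.85 * H), int(0.42 * W) : int(0.58 * W)] = True  # stem
    return mask


def _stamp_segment(mask, p0, p1, width):
    """Set pixels within width/2 of the segment p0-p1 (points are (row, col))."""
    H, W = mask.shape
    ii, jj = np.indices((H, W))
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = (ii - p0[0]) ** 2 + (jj - p0[1]) ** 2
    else:
        t = np.clip(((ii - p0[0]) * d[0] + (jj - p0[1]) * d[1]) / L2, 0.0, 1.0)
        dist2 = (ii - (p0[0] + t * d[0])) ** 2 + (jj - (p0[1] + t * d[1])) ** 2
    mask |= dist2 <= (width / 2.0) ** 2


def _vessel_mask(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """Recursive branching tree, 3 levels, widths 5 -> 3 -> 2 pixels."""
    mask = np.zeros((H, W), dtype=bool)
    widths = (5.0, 3.0, 2.0)
    lengths = (0.35 * H, 0.25 * H, 0.18 * H)

    def grow(p0, angle, level):
        if level >= len(widths):
            return
        length = lengths[level]
        p1 = (p0[0] - length * np.cos(angle), p0[1] + length * np.sin(angle))
        _stamp_segment(mask, p0, p1, widths[level])
        spread = np.deg2rad(28.0)
        for sign in (-1.0, 1.0):
            jitter = rng.uniform(-0.15, 0.15)
            grow(p1, angle + sign * spread + jitter, level + 1)

    grow((H - 2.0, W / 2.0), rng.uniform(-0.1, 0.1), 0)
    return mask


def _blob_mask(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed-random closed region: largest component of a thresholded smooth field."""
    g = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=min(H, W) / 8.0)
    mask = g > np.percentile(g, 60.0)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _bias_pattern(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth pattern normalised to [-1, 1]: low-order polynomial or one sinusoid."""
    yy, xx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W), indexing="ij")
    if rng.integers(2) == 0:
        c = rng.uniform(-1, 1, size=5)
        p = c[0] * xx + c[1] * yy + c[2] * xx * yy + c[3] * xx**2 + c[4] * yy**2
    else:
        k = rng.uniform(0.5, 1.2)  # cycles across the frame
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        p = np.sin(np.pi * k * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    ptp = p.max() - p.min()
    if ptp < 1e-12:
        return np.zeros((H, W))
    return 2.0 * (p - p.min()) / ptp - 1.0


def make_phantom(
    shape: str = "blob",
    size=(128, 128),
    fg_level: float = 0.75,
    bg_level: float = 0.25,
    bias_amplitude: float = 0.5,
    noise_sigma: float = 0.02,
    seed: int = 7,
) -> Phantom:
    """Generate a two-region phantom with multiplicative bias and additive noise.

    ``bias_amplitude`` must lie in [0, 1) so the bias field stays positive;
    0 together with ``noise_sigma = 0`` yields an exactly two-valued image.
    """
    if shape not in SHAPES:
        raise ValueError(f"shape must be one of {SHAPES}, got {shape!r}")
    if isinstance(size, int):
        size = (size, size)
    H, W = int(size[0]), int(size[1])
    if H < 8 or W < 8:
        raise ValueError("phantom size must be at least 8x8")
    if not (0.0 <= bg_level < fg_level <= 1.0):
        raise ValueError("need 0 <= bg_level < fg_level <= 1")
    if not (0.0 <= bias_amplitude < 1.0):
        raise ValueError("bias_amplitude must lie in [0, 1) to keep the bias positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    rng = np.random.default_rng(seed)
    if shape == "disk":
        truth = _disk_mask(H, W)
    elif shape == "T_shape":
        truth = _t_mask(H, W)
    elif shape == "vessel_tree":
        truth = _vessel_mask(H, W, rng)
    else:
        truth = _blob_mask(H, W, rng)

    bias = 1.0 + bias_amplitude * _bias_pattern(H, W, rng)
    base = np.where(truth, fg_level, bg_level).astype(np.float64)
    image = base * bias
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=(H, W))
    image = np.clip(image, 0.0, 1.0)
    return Phantom(
        image=image,
        truth_mask=truth.astype(np.uint8),
        bias_field=bias,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


def bias_blob_128() -> Phantom:
    """The named acceptance fixture: 128x128 blob, fg 0.75 / bg 0.25, bias 0.5, noise 0.02, seed 7."""
    return make_phantom("blob", (128, 128), 0.75, 0.25, 0.5, 0.02, 7)


#: named fixture registry: name -> zero-argument factory
FIXTURES = {
    "clean_disk_64": lambda: make_phantom("disk", (64, 64), 0.8, 0.2, 0.0, 0.0, 1),
    "t_shape_64": lambda: make_phantom("T_shape", (64, 64), 0.75, 0.25, 0.4, 0.02, 3),
    "vessel_96": lambda: make_phantom("vessel_tree", (96, 96), 0.75, 0.25, 0.4, 0.02, 5),
    "bias_blob_128": bias_blob_128,
}


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = _as_binary(mask_a, "mask_a")
    b = _as_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def jaccard(mask_a, mask_b) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a = _as_binary(mask_a, "mask_a")
    b = _as_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union
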