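"""Soft-thresholding (shrinkage) operators.

``shrink_scalar(q, t)`` is the closed-form minimiser of
``t*|w| + 0.5*(w - q)**2`` per pixel; ``shrink_vector`` is the analogous
minimiser of ``t*|w| + 0.5*|w - q|**2`` with the Euclidean magnitude, which
shrinks the magnitude and preserves the direction.  Every Split Bregman
subproblem with an L1 term reduces to one of these.

Where the magnitude is numerically zero the result is exactly the zero
vector (the shrinkage output is zero there for any positive threshold, and
this avoids dividing by a vanishing magnitude).
"""

from __future__ import annotations

import numpy as np

from .grid import VectorField

__all__ = ["shrink_scalar", "shrink_vector"]

#: magnitudes below this are treated as exactly zero (division guard)
_MAG_EPS = 1e-12


def _check_threshold(t: float) -> float:
    t = float(t)
    if not np.isfinite(t) or t <= 0:
        raise ValueError(f"shrinkage threshold must be positive, got {t}")
    return t


def shrink_scalar(q, t: float) -> np.ndarray:
    """Per-pixel soft threshold: ``sign(q) * max(|q| - t, 0)``."""
    t = _check_threshold(t)
    q = np.asarray(q, dtype=np.float64)
    return np.sign(q) * np.maximum(np.abs(q) - t, 0.0)


def shrink_vector(q: VectorField, t: float) -> VectorField:
    """Vector soft threshold: shrink the Euclidean magnitude, keep the direction."""
    t = _check_threshold(t)
    mag = q.magnitude()
    safe = np.where(mag > _MAG_EPS, mag, 1.0)
    scale = np.where(mag > _MAG_EPS, np.maximum(mag - t, 0.0) / safe, 0.0)
    return VectorField(scale * q.x, scale * q.y)
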