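"""Discrete differential operators on the pixel lattice.

All fields are 2-D float arrays indexed ``(row i, column j)`` = ``(y, x)``,
0-based, with unit pixel spacing.  The gradient uses forward differences
with a replicated (Neumann) boundary, so the difference across the last
row/column is zero; the divergence is its exact negative adjoint (backward
differences with the matching boundary), which makes the discrete
integration-by-parts identity

    <grad u, p> = -<u, div p>

hold to floating round-off.  This is the standard adjoint pair used in
total-variation solvers; it makes the shrinkage optimality conditions of
the Split Bregman subproblems exact.

The Laplacian is defined as ``divergence(gradient(u))`` (the 5-point
stencil on the interior, Neumann-adjusted at the boundary) and is computed
through exactly that composition, so the identity holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VectorField", "gradient", "divergence", "laplacian", "as_grid"]


def as_grid(u, name: str = "field") -> np.ndarray:
    """Validate and coerce ``u`` to a finite 2-D float64 array."""
    arr = np.asarray(u, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"{name} must be at least 3x3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class VectorField:
    """A per-pixel 2-vector: ``x`` is the column (j) component, ``y`` the row (i) component."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        if np.shape(self.x) != np.shape(self.y):
            raise ValueError(
                f"component shape mismatch: {np.shape(self.x)} vs {np.shape(self.y)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    @classmethod
    def zeros(cls, shape) -> "VectorField":
        return cls(np.zeros(shape), np.zeros(shape))

    def magnitude(self) -> np.ndarray:
        """Per-pixel Euclidean magnitude sqrt(x^2 + y^2)."""
        return np.hypot(self.x, self.y)

    def __add__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.x - other.x, self.y - other.y)

    def __mul__(self, scalar) -> "VectorField":
        return VectorField(self.x * scalar, self.y * scalar)

    __rmul__ = __mul__

    def copy(self) -> "VectorField":
        return VectorField(self.x.copy(), self.y.copy())


def gradient(u) -> VectorField:
    """Forward-difference gradient with replicated (Neumann) boundary.

    The difference across the last column (x) / last row (y) is zero.
    """
    u = as_grid(u, "u")
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    return VectorField(gx, gy)


def divergence(p: VectorField) -> np.ndarray:
    """Backward-difference divergence, the exact negative adjoint of :func:`gradient`."""
    px = as_grid(p.x, "p.x")
    py = as_grid(p.y, "p.y")
    if px.shape != py.shape:
        raise ValueError("vector field components must share a shape")
    div = np.zeros_like(px)
    # x part: adjoint of forward differences that are zeroed on the last column
    div[:, 0] += px[:, 0]
    div[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    div[:, -1] += -px[:, -2]
    # y part
    div[0, :] += py[0, :]
    div[1:-1, :] += py[1:-1, :] - py[:-2, :]
    div[-1, :] += -py[-2, :]
    return div


def laplacian(u) -> np.ndarray:
    """Discrete Laplacian, defined (and computed) as ``divergence(gradient(u))``."""
    return divergence(gradient(u))
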