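"""Contour (phi) subproblem.

With the region approximations fixed, the relaxed indicator phi ∈ [0,1]
minimises  ∫|∇phi| + ∫ R phi,  where R is the region competition residual.
Split Bregman introduces v ≈ ∇phi with accumulator d; the phi update is a
semi-implicit step of the descent PDE

    dphi/dt = lam (Δphi + ∇·d - ∇·v) - R

followed by projection onto [0,1]; v is a vector shrinkage with threshold
1/lam and d accumulates the constraint defect.  Because the relaxed
problem is convex, the minimiser does not depend on how phi is
initialised; thresholding at ``th`` recovers a binary mask with 1 marking
the foreground (region 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VectorField, as_grid, divergence, gradient
from .params import ModelParams
from .shrinkage import shrink_vector

__all__ = [
    "LevelSetField",
    "init_levelset",
    "project_phi",
    "update_phi",
    "update_v",
    "update_d",
    "binarize",
    "solve_phi",
    "phi_objective",
]


@dataclass
class LevelSetField:
    """phi ∈ [0,1] with its Split Bregman auxiliaries v ≈ ∇phi and accumulator d."""

    phi: np.ndarray
    v: VectorField
    d: VectorField

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.phi.copy(), self.v.copy(), self.d.copy())


def init_levelset(phi0) -> LevelSetField:
    """Start from a given phi (clamped to [0,1]) with v = ∇phi, d = 0."""
    phi = project_phi(as_grid(phi0, "phi0"))
    return LevelSetField(phi, gradient(phi), VectorField.zeros(phi.shape))


def project_phi(phi) -> np.ndarray:
    """Pointwise projection onto [0,1] (the nearest point per pixel)."""
    return np.clip(np.asarray(phi, dtype=np.float64), 0.0, 1.0)


def _neighbour_sum(u: np.ndarray) -> np.ndarray:
    """Sum of the 4 neighbours with replicated (Neumann) boundary."""
    up = np.concatenate([u[:1], u[:-1]], axis=0)
    down = np.concatenate([u[1:], u[-1:]], axis=0)
    left = np.concatenate([u[:, :1], u[:, :-1]], axis=1)
    right = np.concatenate([u[:, 1:], u[:, -1:]], axis=1)
    return up + down + left + right


def update_phi(R, ls: LevelSetField, lam: float, dt: float, scheme: str = "consistent") -> np.ndarray:
    """One semi-implicit phi step, immediately projected onto [0,1].

    ``consistent`` (default):
        phi <- (phi + dt*(lam*(N4(phi) + ∇·d - ∇·v) - R)) / (1 + 4*lam*dt)
    ``literal``:
        phi <- dt/(1 + 4*lam*dt) * (lam*(N4(phi) + ∇·d - ∇·v) - R)
    The literal variant drops the +phi carry; it is retained only for
    comparison and does not reduce to the descent PDE as dt -> 0.
    """
    if not lam > 0 or not dt > 0:
        raise ValueError("lam and dt must be positive")
    R = as_grid(R, "R")
    drive = lam * (_neighbour_sum(ls.phi) + divergence(ls.d) - divergence(ls.v)) - R
    if scheme == "consistent":
        phi_new = (ls.phi + dt * drive) / (1.0 + 4.0 * lam * dt)
    elif scheme == "literal":
        phi_new = dt / (1.0 + 4.0 * lam * dt) * drive
    else:
        raise ValueError(f"unknown phi scheme {scheme!r}")
    return project_phi(phi_new)


def update_v(ls: LevelSetField, lam: float) -> VectorField:
    """Vector shrinkage of ∇phi + d with threshold 1/lam."""
    if not lam > 0:
        raise ValueError("lam must be positive")
    return shrink_vector(gradient(ls.phi) + ls.d, 1.0 / lam)


def update_d(ls: LevelSetField) -> VectorField:
    """Bregman accumulator update d <- d + ∇phi - v."""
    return ls.d + gradient(ls.phi) - ls.v


def binarize(phi, th: float = 0.5) -> np.ndarray:
    """Threshold phi into a {0,1} mask: 1 (foreground) where phi >= th."""
    if not 0.0 < th < 1.0:
        raise ValueError(f"th must lie in (0, 1), got {th}")
    phi = as_grid(phi, "phi")
    return (phi >= th).astype(np.uint8)


def phi_objective(R, phi) -> float:
    """Contour objective ∫|∇phi| + ∫ R phi for a fixed residual R."""
    phi = as_grid(phi, "phi")
    R = as_grid(R, "R")
    return float(gradient(phi).magnitude().sum() + (R * phi).sum())


def solve_phi(R, ls: LevelSetField, params: ModelParams) -> LevelSetField:
    """Run ``n_inner_phi`` cycles of (phi step, v shrinkage, d update).

    Early exit when the relative L1 change of phi drops below ``params.tol``.
    """
    ls = ls.copy()
    for _ in range(params.n_inner_phi):
        phi_prev = ls.phi
        ls.phi = update_phi(R, ls, params.lam, params.dt, params.phi_scheme)
        ls.v = update_v(ls, params.lam)
        ls.d = update_d(ls)
        denom = max(float(np.abs(phi_prev).sum()), 1e-12)
        if float(np.abs(ls.phi - phi_prev).sum()) / denom <= params.tol:
            break
    return ls
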