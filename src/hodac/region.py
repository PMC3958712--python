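"""Region-approximation subproblem (Split Bregman).

For a fixed relaxed indicator ``phi`` the smooth region field ``u`` minimises

    ∫ (alpha |f-u|^2 + beta |∇u| + gamma |Δu|) phi

which, after introducing auxiliary variables w1 ≈ ∇u (vector) and
w2 ≈ Δu = ∇·w1 (scalar) with a Bregman accumulator b1 for the gradient
constraint, splits into

  * a linear solve for u (Gauss-Seidel sweeps of the discretised
    Euler-Lagrange equation, phi-weighted fidelity, unweighted diffusion),
  * a vector shrinkage for w1 (threshold beta/mu, with the lagged
    higher-order coupling term (theta/mu) ∇(∇·w1 - w2) inside the
    argument and its magnitude),
  * a scalar shrinkage for w2 (threshold gamma/theta applied to ∇·w1),
  * the Bregman update b1 <- b1 + ∇u - w1.

The u2 subproblem is the same with mask 1-phi and its own weights; both
share mu1/theta1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .grid import VectorField, as_grid, divergence, gradient, laplacian
from .params import ModelParams
from .shrinkage import shrink_scalar, shrink_vector

__all__ = [
    "RegionState",
    "init_region_state",
    "update_u",
    "update_w1",
    "update_w2",
    "update_b1",
    "solve_region",
    "region_objective",
    "region_residual",
]


@dataclass
class RegionState:
    """Iterate of one region subproblem: u, w1 ≈ ∇u, w2 ≈ ∇·w1, Bregman b1."""

    u: np.ndarray
    w1: VectorField
    w2: np.ndarray
    b1: VectorField

    def copy(self) -> "RegionState":
        return RegionState(self.u.copy(), self.w1.copy(), self.w2.copy(), self.b1.copy())


def init_region_state(u0) -> RegionState:
    """Constraint-consistent start: w1 = ∇u0, w2 = ∇·w1, b1 = 0."""
    u0 = as_grid(u0, "u0")
    w1 = gradient(u0)
    return RegionState(u0.copy(), w1, divergence(w1), VectorField.zeros(u0.shape))


@njit(cache=False)
def _gauss_seidel_sweep(u, f, phi, c, alpha, mu):  # pragma: no cover - numba
    """One in-place lexicographic Gauss-Seidel sweep.

    u[i,j] <- (2*alpha*phi*f + mu*(sum of 4 neighbours + c)) / (2*alpha*phi + 4*mu)
    with out-of-bounds neighbours replicated (Neumann).  c = ∇·(b1 - w1).
    """
    H, W = u.shape
    for i in range(H):
        for j in range(W):
            un = u[i - 1, j] if i > 0 else u[i, j]
            us = u[i + 1, j] if i < H - 1 else u[i, j]
            uw = u[i, j - 1] if j > 0 else u[i, j]
            ue = u[i, j + 1] if j < W - 1 else u[i, j]
            ap = 2.0 * alpha * phi[i, j]
            u[i, j] = (ap * f[i, j] + mu * (un + us + uw + ue + c[i, j])) / (ap + 4.0 * mu)


def _check_mask(phi_mask) -> np.ndarray:
    phi_mask = as_grid(phi_mask, "phi_mask")
    if phi_mask.min() < -1e-12 or phi_mask.max() > 1 + 1e-12:
        raise ValueError("phi_mask values must lie in [0, 1]")
    return np.clip(phi_mask, 0.0, 1.0)


def update_u(f, state: RegionState, phi_mask, alpha: float, mu: float) -> np.ndarray:
    """One Gauss-Seidel sweep of the u fixed point; returns the new u."""
    if not alpha > 0 or not mu > 0:
        raise ValueError("alpha and mu must be positive")
    f = as_grid(f, "f")
    phi_mask = _check_mask(phi_mask)
    c = divergence(state.b1 - state.w1)
    u = state.u.copy()
    _gauss_seidel_sweep(u, f, phi_mask, c, float(alpha), float(mu))
    return u


def update_w1(u, state: RegionState, beta: float, mu: float, theta: float) -> VectorField:
    """Vector shrinkage of ∇u + b1 + (theta/mu) ∇(∇·w1 - w2), threshold beta/mu.

    The higher-order coupling term is evaluated at the lagged (previous
    inner-iteration) w1, w2 held in ``state``.  beta = 0 returns the
    argument unshrunk (no total-variation penalty).
    """
    if not mu > 0 or not theta >= 0 or beta < 0:
        raise ValueError("need mu > 0, theta >= 0, beta >= 0")
    arg = gradient(u) + state.b1
    if theta > 0:
        arg = arg + (theta / mu) * gradient(divergence(state.w1) - state.w2)
    if beta == 0:
        return arg
    return shrink_vector(arg, beta / mu)


def update_w2(state: RegionState, gamma: float, theta: float) -> np.ndarray:
    """Scalar shrinkage of ∇·w1 with threshold gamma/theta (gamma = 0: no shrink)."""
    if not theta > 0 or gamma < 0:
        raise ValueError("need theta > 0, gamma >= 0")
    div_w1 = divergence(state.w1)
    if gamma == 0:
        return div_w1
    return shrink_scalar(div_w1, gamma / theta)


def update_b1(state: RegionState, u) -> VectorField:
    """Bregman accumulator update b1 <- b1 + ∇u - w1 (w1 already updated)."""
    return state.b1 + gradient(u) - state.w1


def region_objective(f, state: RegionState, phi_mask, alpha, beta, gamma, mu, theta) -> float:
    """Masked splitting objective evaluated at the current iterate.

    ∫ (beta|w1| + gamma|w2| + alpha(f-u)^2) phi
      + (mu/2)∫ |w1 - ∇u - b1|^2 + (theta/2)∫ (w2 - ∇·w1)^2
    """
    f = as_grid(f, "f")
    phi_mask = _check_mask(phi_mask)
    fit = alpha * (f - state.u) ** 2 + beta * state.w1.magnitude() + gamma * np.abs(state.w2)
    cons1 = state.w1 - gradient(state.u) - state.b1
    pen = 0.5 * mu * (cons1.x**2 + cons1.y**2) + 0.5 * theta * (state.w2 - divergence(state.w1)) ** 2
    return float(np.sum(fit * phi_mask) + np.sum(pen))


def _weights(params: ModelParams, which: int) -> tuple[float, float, float]:
    if which == 1:
        return params.alpha1, params.beta1, params.gamma1
    if which == 2:
        return params.alpha2, params.beta2, params.gamma2
    raise ValueError(f"which must be 1 or 2, got {which}")


def solve_region(
    f,
    phi_mask,
    params: ModelParams,
    which: int = 1,
    state: RegionState | None = None,
    objective_trace: list | None = None,
) -> RegionState:
    """Run ``n_inner_region`` Bregman cycles of the region subproblem.

    Each cycle is (u sweep, w1 shrinkage, w2 shrinkage, b1 update).  A
    warm-start ``state`` may be passed (the outer alternation does); the
    default start is u = f with constraint-consistent auxiliaries.  Early
    exit when the relative L1 change of u drops below ``params.tol``.
    """
    alpha, beta, gamma = _weights(params, which)
    mu, theta = params.mu1, params.theta1
    f = as_grid(f, "f")
    if state is None:
        state = init_region_state(f)
    else:
        state = state.copy()
    for cycle in range(params.n_inner_region):
        u_prev = state.u
        state.u = update_u(f, state, phi_mask, alpha, mu)
        state.w1 = update_w1(state.u, state, beta, mu, theta)
        state.w2 = update_w2(state, gamma, theta)
        state.b1 = update_b1(state, state.u)
        if objective_trace is not None:
            objective_trace.append(
                region_objective(f, state, phi_mask, alpha, beta, gamma, mu, theta)
            )
        # the u sweep runs before the w/b updates, so the first cycle's
        # u-change is blind to them; never exit on cycle 0
        denom = max(float(np.abs(u_prev).sum()), 1e-12)
        if cycle > 0 and float(np.abs(state.u - u_prev).sum()) / denom <= params.tol:
            break
    return state


def region_residual(f, s1: RegionState, s2: RegionState, params: ModelParams) -> np.ndarray:
    """Per-pixel competition term R driving the contour:

    R = (a1|f-u1|^2 + b1|∇u1| + g1|Δu1|) - (a2|f-u2|^2 + b2|∇u2| + g2|Δu2|)

    Negative R favours region 1 (foreground), positive favours region 2.
    """
    f = as_grid(f, "f")

    def side(state, alpha, beta, gamma):
        return (
            alpha * (f - state.u) ** 2
            + beta * gradient(state.u).magnitude()
            + gamma * np.abs(laplacian(state.u))
        )

    return side(s1, params.alpha1, params.beta1, params.gamma1) - side(
        s2, params.alpha2, params.beta2, params.gamma2
    )
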