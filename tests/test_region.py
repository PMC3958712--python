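"""Region subproblem: Gauss-Seidel fixed point, shrinkage updates, residual."""

import numpy as np
import pytest

from hodac.grid import VectorField, divergence, gradient, laplacian
from hodac.params import ModelParams
from hodac.phantoms import make_phantom
from hodac.region import (
    RegionState,
    init_region_state,
    region_residual,
    solve_region,
    update_b1,
    update_u,
    update_w1,
    update_w2,
)
from hodac.shrinkage import shrink_scalar, shrink_vector


def dense_system(phi, alpha, mu, f, c):
    """Assemble (2*alpha*Phi + mu*L) u = 2*alpha*Phi f + mu*(c + boundary) densely.

    L is the Neumann 5-point Laplacian implied by replicated neighbours.
    """
    h, w = f.shape
    n = h * w
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(h):
        for j in range(w):
            p = i * w + j
            A[p, p] = 2.0 * alpha * phi[i, j] + 4.0 * mu
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w:
                    A[p, ni * w + nj] -= mu
                else:
                    A[p, p] -= mu  # replicated neighbour folds onto the diagonal
            rhs[p] = 2.0 * alpha * phi[i, j] * f[i, j] + mu * c[i, j]
    return A, rhs


def fresh_state(u, w1=None, w2=None, b1=None):
    shape = u.shape
    return RegionState(
        u.copy(),
        w1 if w1 is not None else VectorField.zeros(shape),
        w2 if w2 is not None else np.zeros(shape),
        b1 if b1 is not None else VectorField.zeros(shape),
    )


def test_update_u_constant_fixed_point():
    f = np.full((5, 5), 0.4)
    state = fresh_state(f)
    out = update_u(f, state, np.ones((5, 5)), alpha=1.0, mu=1.0)
    np.testing.assert_allclose(out, 0.4, atol=1e-14)


def test_update_u_first_pixel_matches_formula():
    """The sweep is in-place lexicographic, so pixel (0,0) sees only old values."""
    rng = np.random.default_rng(7)
    u = rng.uniform(0, 1, (3, 3))
    f = rng.uniform(0, 1, (3, 3))
    phi = rng.uniform(0, 1, (3, 3))
    w1 = VectorField(rng.standard_normal((3, 3)), rng.standard_normal((3, 3)))
    b1 = VectorField(rng.standard_normal((3, 3)), rng.standard_normal((3, 3)))
    state = fresh_state(u, w1=w1, b1=b1)
    alpha, mu = 1.5, 2.0
    c = divergence(b1 - w1)
    out = update_u(f, state, phi, alpha, mu)
    # replicated out-of-bounds neighbours fold onto the centre value
    n4 = u[0, 0] + u[1, 0] + u[0, 0] + u[0, 1]
    ap = 2.0 * alpha * phi[0, 0]
    expected = (ap * f[0, 0] + mu * (n4 + c[0, 0])) / (ap + 4.0 * mu)
    assert out[0, 0] == pytest.approx(expected, rel=1e-12)
    # known arithmetic case: neighbours {1,1,1,1}, f = 1, alpha = mu = 1 -> u = 1
    ones = np.ones((3, 3))
    out = update_u(ones, fresh_state(ones), ones, 1.0, 1.0)
    assert out[1, 1] == pytest.approx((2.0 * 1 + 1.0 * 4) / (2.0 + 4.0))


@pytest.mark.parametrize("masked", [False, True])
def test_gauss_seidel_converges_to_dense_solution(masked):
    """Repeated sweeps solve the discretised Euler-Lagrange system to 1e-8."""
    rng = np.random.default_rng(8)
    h = w = 10
    f = rng.uniform(0, 1, (h, w))
    phi = rng.uniform(0, 1, (h, w)) if masked else np.ones((h, w))
    w1 = VectorField(rng.standard_normal((h, w)), rng.standard_normal((h, w)))
    b1 = VectorField(rng.standard_normal((h, w)), rng.standard_normal((h, w)))
    state = fresh_state(f, w1=w1, b1=b1)
    alpha, mu = 1.0, 1.0
    c = divergence(b1 - w1)
    A, rhs = dense_system(phi, alpha, mu, f, c)
    expected = np.linalg.solve(A, rhs).reshape(h, w)
    for _ in range(2000):
        state.u = update_u(f, state, phi, alpha, mu)
    err = np.abs(state.u - expected).max() / max(np.abs(expected).max(), 1e-12)
    assert err <= 1e-8


def test_update_u_rejects_bad_weights():
    state = fresh_state(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        update_u(np.zeros((3, 3)), state, np.ones((3, 3)), alpha=0.0, mu=1.0)


def test_update_w1_full_shrinkage_for_large_beta():
    rng = np.random.default_rng(2)
    u = rng.uniform(0, 1, (4, 4))
    state = init_region_state(u)
    out = update_w1(u, state, beta=1e6, mu=1.0, theta=1.0)
    assert np.all(out.x == 0.0) and np.all(out.y == 0.0)


def test_update_w1_theta_zero_is_plain_tv_shrinkage():
    rng = np.random.default_rng(4)
    u = rng.uniform(0, 1, (4, 4))
    b1 = VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4)))
    state = fresh_state(u, b1=b1)
    out = update_w1(u, state, beta=0.3, mu=1.0, theta=0.0)
    expected = shrink_vector(gradient(u) + b1, 0.3)
    np.testing.assert_allclose(out.x, expected.x)
    np.testing.assert_allclose(out.y, expected.y)


def test_update_w1_matches_independently_assembled_argument():
    rng = np.random.default_rng(6)
    u = rng.uniform(0, 1, (4, 4))
    state = RegionState(
        u,
        VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4))),
        rng.standard_normal((4, 4)),
        VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4))),
    )
    beta, mu, theta = 0.2, 2.0, 0.5
    arg = gradient(u) + state.b1 + (theta / mu) * gradient(divergence(state.w1) - state.w2)
    expected = shrink_vector(arg, beta / mu)
    out = update_w1(u, state, beta, mu, theta)
    np.testing.assert_allclose(out.x, expected.x)
    np.testing.assert_allclose(out.y, expected.y)


def test_update_w2_zero_and_full_shrinkage():
    state = fresh_state(np.zeros((4, 4)))
    assert np.all(update_w2(state, gamma=0.5, theta=1.0) == 0.0)
    rng = np.random.default_rng(9)
    state = fresh_state(
        np.zeros((4, 4)),
        w1=VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4))),
    )
    big = np.abs(divergence(state.w1)).max() + 1.0
    assert np.all(update_w2(state, gamma=big, theta=1.0) == 0.0)


def test_update_w2_matches_scalar_minimisation_oracle():
    """Per pixel, w2 minimises gamma*|w| + theta/2 (w - div w1)^2."""
    rng = np.random.default_rng(10)
    state = fresh_state(
        np.zeros((4, 4)),
        w1=VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4))),
    )
    gamma, theta = 0.4, 1.3
    out = update_w2(state, gamma, theta)
    grid = np.arange(-10, 10, 1e-4)
    for val, q in zip(out.ravel(), divergence(state.w1).ravel()):
        best = grid[np.argmin(gamma * np.abs(grid) + 0.5 * theta * (grid - q) ** 2)]
        assert abs(val - best) <= 2e-4


def test_update_b1_constraint_satisfied_is_noop():
    rng = np.random.default_rng(12)
    u = rng.uniform(0, 1, (4, 4))
    state = fresh_state(u, w1=gradient(u))
    out = update_b1(state, u)
    np.testing.assert_allclose(out.x, 0.0, atol=1e-15)
    np.testing.assert_allclose(out.y, 0.0, atol=1e-15)


def test_update_b1_accumulates_running_sum():
    rng = np.random.default_rng(13)
    state = fresh_state(np.zeros((4, 4)))
    total_x = np.zeros((4, 4))
    total_y = np.zeros((4, 4))
    for _ in range(4):
        u = rng.uniform(0, 1, (4, 4))
        state.w1 = VectorField(rng.standard_normal((4, 4)), rng.standard_normal((4, 4)))
        g = gradient(u)
        total_x += g.x - state.w1.x
        total_y += g.y - state.w1.y
        state.b1 = update_b1(state, u)
    np.testing.assert_allclose(state.b1.x, total_x)
    np.testing.assert_allclose(state.b1.y, total_y)


def test_solve_region_pure_fidelity_limit():
    """With beta = gamma = 0 and weak diffusion, u converges to f."""
    rng = np.random.default_rng(14)
    f = rng.uniform(0, 1, (8, 8))
    p = ModelParams(beta1=0.0, gamma1=0.0, mu1=1e-3, n_inner_region=200, tol=0.0)
    state = solve_region(f, np.ones((8, 8)), p, which=1, state=init_region_state(np.zeros((8, 8))))
    assert np.abs(state.u - f).max() < 1e-3


def test_solve_region_recovers_masked_means():
    """Piecewise-constant image with the true indicator: u1/u2 near the region means."""
    ph = make_phantom("disk", (32, 32), 0.8, 0.2, 0.0, 0.0, 2)
    f, phi = ph.image, ph.truth_mask.astype(float)
    # a data-tracking regime: diffusion length sqrt(mu/2 alpha) well below the
    # disk radius, so the masked fit reaches the region level
    p = ModelParams(alpha1=4.0, alpha2=4.0, mu1=2.0, n_inner_region=200, tol=1e-9)
    s1 = solve_region(f, phi, p, which=1, state=init_region_state(np.full(f.shape, 0.7)))
    s2 = solve_region(f, 1 - phi, p, which=2, state=init_region_state(np.full(f.shape, 0.3)))
    fg_mean = f[phi == 1].mean()
    bg_mean = f[phi == 0].mean()
    assert abs(s1.u[phi == 1].mean() - fg_mean) <= 0.01 * fg_mean
    assert abs(s2.u[phi == 0].mean() - bg_mean) <= 0.01 * bg_mean


def test_solve_region_objective_descends_after_burn_in():
    ph = make_phantom("disk", (32, 32), 0.8, 0.2, 0.3, 0.02, 2)
    p = ModelParams(n_inner_region=40)
    trace = []
    solve_region(
        ph.image,
        ph.truth_mask.astype(float),
        p,
        which=1,
        state=init_region_state(np.full(ph.image.shape, 0.7)),
        objective_trace=trace,
    )
    tr = np.array(trace)
    d = np.diff(tr)
    assert np.all(d[3:] <= 1e-6 * np.abs(tr[3:-1]))


def test_solve_region_symmetry_under_index_swap():
    """Swapping mask, index and weights swaps the roles of u1 and u2 exactly."""
    rng = np.random.default_rng(15)
    f = rng.uniform(0, 1, (10, 10))
    phi = rng.uniform(0, 1, (10, 10))
    p = ModelParams(alpha1=2.0, alpha2=4.0, beta1=0.1, beta2=0.3, gamma1=0.02, gamma2=0.07)
    swapped = p.replace(
        alpha1=p.alpha2, alpha2=p.alpha1, beta1=p.beta2, beta2=p.beta1,
        gamma1=p.gamma2, gamma2=p.gamma1,
    )
    a = solve_region(f, phi, p, which=1, state=init_region_state(f))
    b = solve_region(f, phi, swapped, which=2, state=init_region_state(f))
    assert np.array_equal(a.u, b.u)
    assert np.array_equal(a.w2, b.w2)
    assert np.array_equal(a.w1.x, b.w1.x) and np.array_equal(a.b1.y, b.b1.y)


def test_region_residual_cancels_for_identical_states():
    rng = np.random.default_rng(16)
    f = rng.uniform(0, 1, (6, 6))
    s = init_region_state(rng.uniform(0, 1, (6, 6)))
    p = ModelParams(alpha1=1.0, alpha2=1.0, beta1=0.1, beta2=0.1, gamma1=0.05, gamma2=0.05)
    np.testing.assert_allclose(region_residual(f, s, s, p), 0.0, atol=1e-15)


def test_region_residual_sign_favours_matching_region():
    f = np.full((6, 6), 0.8)
    s1 = init_region_state(np.full((6, 6), 0.8))  # u1 = f
    s2 = init_region_state(np.full((6, 6), 0.2))  # u2 != f
    p = ModelParams(beta1=1e-9, beta2=1e-9, gamma1=1e-9, gamma2=1e-9)
    assert np.all(region_residual(f, s1, s2, p) < 0)


def test_region_residual_matches_independent_reassembly():
    rng = np.random.default_rng(17)
    f = rng.uniform(0, 1, (7, 7))
    s1 = init_region_state(rng.uniform(0, 1, (7, 7)))
    s2 = init_region_state(rng.uniform(0, 1, (7, 7)))
    p = ModelParams(alpha1=1.5, alpha2=0.7, beta1=0.2, beta2=0.05, gamma1=0.03, gamma2=0.11)

    def side(u, a, b, g):
        gx = gradient(u)
        return a * (f - u) ** 2 + b * np.hypot(gx.x, gx.y) + g * np.abs(laplacian(u))

    expected = side(s1.u, p.alpha1, p.beta1, p.gamma1) - side(s2.u, p.alpha2, p.beta2, p.gamma2)
    np.testing.assert_allclose(region_residual(f, s1, s2, p), expected)
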