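# Methods

## Model

`hodac` segments a single-channel image `f : Ω → [0,1]` into two regions
by minimising

    E(u1, u2, φ) = ∫|∇φ|
                 + ∫ (α1|f−u1|² + β1|∇u1| + γ1|Δu1|) φ
                 + ∫ (α2|f−u2|² + β2|∇u2| + γ2|Δu2|) (1−φ),   φ ∈ [0,1].

`u1` and `u2` are smooth approximations of the image inside the
foreground and background; the `β|∇u|` and `γ|Δu|` terms regularise them
with total variation plus a second-order (Laplacian) diffusion penalty,
which is what lets each region follow a smooth intensity drift (bias
field) instead of assuming a constant gray level.  The binary indicator
is relaxed to `φ ∈ [0,1]`, which makes the contour subproblem convex: for
a fixed region residual

    R = (α1|f−u1|² + β1|∇u1| + γ1|Δu1|) − (α2|f−u2|² + β2|∇u2| + γ2|Δu2|)

the minimising `φ` is independent of its initialisation, and the binary
mask is recovered by thresholding `φ ≥ th` (foreground = 1).

## Discretisation

Pixels are unit-spaced, indexed `(row, column)` 0-based.  The gradient is
forward differences with a replicated (Neumann) boundary — the difference
across the last row/column is zero — and the divergence is its exact
negative adjoint (backward differences), so `⟨∇u, p⟩ = −⟨u, ∇·p⟩` holds
to round-off.  The Laplacian is defined and computed as `div(grad(u))`.
This adjoint pair makes every shrinkage optimality condition exact and
keeps constants in the null space of the operators.

## Split Bregman subproblems

*Region fields.*  For each region, auxiliaries `w⃗1 ≈ ∇u` and
`w2 ≈ ∇·w⃗1 ≈ Δu` with a Bregman accumulator `b⃗1` split the problem into
a linear solve and two shrinkages per cycle:

1. one in-place lexicographic Gauss–Seidel sweep of
   `u ← (2αφ f + μ(Σ neighbours + ∇·(b⃗1 − w⃗1))) / (2αφ + 4μ)`
   with replicated boundary neighbours.  The data fidelity is weighted by
   the indicator (where `φ = 0` the update reduces to pure diffusion and
   stays well-posed because the denominator is at least `4μ`); the
   diffusion term is unweighted,
2. `w⃗1 ← shrink_vector(∇u + b⃗1 + (θ/μ)∇(∇·w⃗1 − w2), β/μ)` with the
   higher-order coupling term evaluated at the lagged iterate, inside
   both the argument and its magnitude,
3. `w2 ← shrink_scalar(∇·w⃗1, γ/θ)`,
4. `b⃗1 ← b⃗1 + ∇u − w⃗1`.

`shrink` is the closed-form minimiser of `t|w| + ½|w − q|²`; magnitudes
below 1e−12 map to exactly zero.  Both regions share the penalties
`μ1, θ1`.

*Contour.*  With `v⃗ ≈ ∇φ` and accumulator `d⃗`, each cycle does a
semi-implicit step

    φ ← clip( (φ + dt·[λ(Σ neighbours(φ) + ∇·d⃗ − ∇·v⃗) − R]) / (1 + 4λ·dt), 0, 1 )

followed by `v⃗ ← shrink_vector(∇φ + d⃗, 1/λ)` and `d⃗ ← d⃗ + ∇φ − v⃗`.
A variant that omits the `+φ` carry (scaling the whole right-hand side by
`dt/(1+4λdt)`) is available as `phi_scheme="literal"`; it is not the
default because it does not reduce to the descent PDE as `dt → 0`.
The projection onto `[0,1]` runs after every step, so `φ` never leaves
the box.

*Outer alternation.*  Each outer cycle computes `R` from the current
region fields, runs `n_inner_phi` contour cycles, then `n_inner_region`
region cycles per side with the region states warm-started across outer
iterations.  The loop stops when the relative L¹ change of `φ` *and* of
both region fields drops below `tol` (the contour can stall for a few
cycles while the region fields still adapt, so φ-change alone would stop
too early), or after `n_outer` cycles with `converged=False`.

*Initialisation.*  `φ⁰ = 0.5` everywhere (any start works — the φ
subproblem is convex and the phantom suite verifies Dice ≥ 0.99 agreement
between uniform, checkerboard and random starts).  The region fields
start from the means of `f` above/below its median (bright/dark
constants).  A data-driven asymmetric start is necessary, not cosmetic: a
perfectly symmetric initialisation (`u1 = u2`) makes the uniform `φ` an
exact stationary point of the alternation (`R ≡ 0` and both fields evolve
identically thereafter).  For scenes with very unbalanced regions (thin
vessels in a large field of view) the median split lands inside the
background class; `segment(..., init_levels=(hi, lo))` overrides it.

## Parameters

| name | default | role |
|---|---|---|
| `alpha1, alpha2` | 4.0 | data fidelity per region (scale of `R` against the fixed TV(φ) weight of 1) |
| `beta1, beta2` | 0.1 | TV penalty on `u1, u2` |
| `gamma1, gamma2` | 0.05 | Laplacian (higher-order) penalty on `u1, u2` |
| `mu1` | 800.0 | Bregman penalty tying `w⃗1` to `∇u` |
| `theta1` | 1.0 | Bregman penalty tying `w2` to `∇·w⃗1` |
| `lam` | 0.1 | Bregman penalty of the contour split (shrink threshold `1/λ`) |
| `dt` | 0.5 | semi-implicit contour step |
| `th` | 0.5 | binarisation threshold |
| `n_outer / n_inner_region / n_inner_phi` | 150 / 5 / 30 | iteration budget |
| `tol` | 1e−4 | relative-change stopping tolerance |

All defaults are engineering choices validated on the phantom suite (the
source formulation reports no parameter values); intensities are assumed
in `[0,1]` (file loading normalises).

Two ratios matter most.  `√(μ/2α)` (≈ 10 px at the defaults) is the
*healing length* of the region fields at finite iteration counts: the
scale below which a field cannot bend to fit intensity detail.  It must
sit between the noise/feature scale and the bias-field scale: much
smaller and a region field can locally re-fit a wrongly captured patch of
the other region, locking the error in and eroding the contour from the
boundary (small `μ` visibly destabilises the clean-disk phantom); much
larger and the fields cannot follow the bias.  Second, `α·Δ²` (level
contrast Δ) against the unit TV(φ) weight sets how small a structure the
contour keeps: thin, low-contrast structures need larger `α`.  The
`θ ≪ μ` default matters for the denoiser too: the higher-order coupling
enters the `w⃗1` shrinkage lagged, and `θ` comparable to `μ` makes that
lag oscillate (the standalone denoiser picks `μ ~ max(2λ1, 1)`,
`θ ≤ μ/10` automatically).

## Chan–Vese baseline and denoiser

`cv_segment` runs the identical pipeline with the region solves replaced
by φ-weighted scalar means (empty regions fall back to the global mean,
logged).  `segment(..., region="means")` with `β = γ = 0` is
field-for-field identical to it — the reduction is by construction, and a
test asserts it.  `hod_denoise` minimises
`½∫(u−f)² + λ1∫|∇u| + λ2∫|Δu|` by running the region machinery with a
full mask and `α = ½`.

## Phantom generator

`make_phantom` emulates the regime the model targets, since comparable
clinical images cannot be bundled: a two-level scene (`bg_level`,
`fg_level`) under a smooth multiplicative bias field
`1 + amplitude · pattern` (pattern a seed-selected low-order polynomial
or single low-frequency sinusoid, normalised to [−1,1]; amplitude < 1
keeps the field positive) plus additive Gaussian noise, clipped to
[0,1].  Geometries: centred disk, T-shape (two rectangles), recursive
vessel tree (3 levels, widths 5→3→2 px — deliberately thin, weak
boundaries), and a smoothed-random blob.  Everything is a pure function
of `(arguments, seed)`.

What the phantoms do *not* emulate: Rician/MRI noise statistics, partial
volume effects, textured backgrounds, and multiplicative noise.  Passing
the suite therefore demonstrates correctness of the solver and robustness
to smooth multiplicative shading with moderate additive noise, not
clinical-grade performance.

The named fixture `bias_blob_128` (128×128 blob, levels 0.75/0.25, bias
amplitude 0.5, noise σ 0.02, seed 7) is the robustness benchmark: the
full model reaches Dice ≈ 0.999 where the means baseline stays ≈ 0.979.
Fixture problem sizes (64–128 px) keep the whole test suite and the
acceptance script in the tens of seconds on one CPU.

## Known limitations

- Thin elongated structures (the vessel-tree phantom) are largely lost at
  the default weights: their area-to-perimeter ratio is too small for the
  unit TV(φ) weight unless `α` is raised substantially, and the median
  initial split misjudges scenes where the foreground is a few percent of
  the frame.  `init_levels` and larger `α` help; the defaults favour the
  compact-region regime.
- The alternation is only convex in `φ` for fixed region fields; the
  joint problem is not convex, and the region-field initialisation (not
  the contour initialisation) carries the basin choice.
- The per-iterate objective of the *inner* Bregman solvers wobbles at the
  ~1e−5 relative level near convergence (accumulator updates are not
  descent steps); the outer energy trace is monotone to 1e−6 after a
  ≤3-cycle burn-in on all shipped fixtures, and the tests check exactly
  that.
- Two-phase only; 3-D volumes, colour images and anisotropic pixel
  spacing are out of scope.
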