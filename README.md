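# hodac — higher-order diffusion active contours

`hodac` segments single-channel images whose intensities drift smoothly
across the frame — the *intensity inhomogeneity* (bias field) typical of
MR coil shading, X-ray angiograms and unevenly lit scenes.  Classical
region-based active contours such as the globally convex Chan–Vese model
describe each region by a single mean gray value, and fail as soon as the
shading makes one region's dark end overlap the other region's bright
end.  `hodac` replaces the scalar means with *smooth region
approximations* regularised by both total variation and a Laplacian
(higher-order diffusion) penalty, so each region can follow its own
shading while the contour stays crisp.

## The model

With `f` the image, `u1, u2` smooth region fields and `φ ∈ [0,1]` a
relaxed region indicator, the segmentation minimises

```
E(u1, u2, φ) = ∫|∇φ|
             + ∫ (α1|f−u1|² + β1|∇u1| + γ1|Δu1|) φ
             + ∫ (α2|f−u2|² + β2|∇u2| + γ2|Δu2|) (1−φ)
```

The relaxation of the binary indicator to `[0,1]` makes the `φ`
subproblem convex, so the contour needs no careful initialisation;
thresholding `φ` at `th` recovers the binary mask.  Every subproblem is
solved with a Split Bregman scheme: auxiliary variables `w⃗1 ≈ ∇u`,
`w2 ≈ Δu` and `v⃗ ≈ ∇φ` turn the L¹ terms into closed-form vector/scalar
soft-thresholding, and the remaining linear problems into Gauss–Seidel
sweeps.  Setting `β = γ = 0` and replacing `u1, u2` by φ-weighted means
recovers the convex Chan–Vese baseline exactly (`cv_segment`), and the
same machinery run with a full mask is a standalone TV + higher-order
diffusion denoiser (`hod_denoise`).

## Worked example

Every solver is testable without downloads through the phantom generator,
which emulates the target regime: a two-level scene under a smooth
multiplicative bias field plus Gaussian noise.

```python
from hodac import ActiveContourModel, cv_segment
from hodac.phantoms import bias_blob_128

phantom = bias_blob_128()          # 128x128 blob, bias ±50%, noise 0.02
res = ActiveContourModel(phantom.image).fit()
print(res.summary())
print("full-model Dice :", round(res.dice(phantom.truth_mask), 4))
print("Chan-Vese Dice  :", round(cv_segment(phantom.image).dice(phantom.truth_mask), 4))
```

prints

```
Active contour segmentation (higher-order diffusion)
==========================================================
image shape          : 128 x 128
outer iterations     : 147
converged            : True
final energy         : 372.813
foreground fraction  : 0.3760
phi range            : [0.0000, 1.0000]
...
full-model Dice : 0.9993
Chan-Vese Dice  : 0.9794
```

The full model recovers the blob almost exactly (Dice 0.9993) while the
means-based baseline misclassifies the shaded corners (Dice 0.9794):
the smooth region fields absorb the bias that breaks the
piecewise-constant assumption.  On an uncorrupted two-level phantom the
recovery is exact (Dice 1.0).

The same functionality is exposed on the command line:

```
hodac phantom --shape blob --size 128 --bias 0.5 --noise 0.02 --seed 7 \
      --out img.png --truth-out truth.png
hodac segment img.png --out mask.png --phi-out phi.npy --log-energy trace.csv
hodac denoise img.png --lambda1 0.1 --lambda2 0.05 --out smooth.png
```

## Layout

- `hodac.grid` — adjoint forward/backward difference operators (Neumann)
- `hodac.shrinkage` — scalar and vector soft thresholding
- `hodac.region` — Split Bregman region-field subproblem
- `hodac.contour` — convex φ subproblem, projection, thresholding
- `hodac.model` — alternating pipeline, `ActiveContourModel` /
  `ChanVeseModel` and `SegmentationResult`, denoiser
- `hodac.phantoms` — ground-truthed phantom generator, Dice/Jaccard
- `hodac.cli`, `hodac.io` — command line and image/config I/O

See `docs/methods.md` for the numerical details and design choices.
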