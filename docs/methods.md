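# Methods

## Model and pipeline

`lumifuse` enhances a low-light RGB image `P` by fusing it with a virtual
second exposure of the same scene. All computation happens on
floating-point values in `[0, 1]`; the camera response involves
`P**(k**a)`, which is only well behaved on the unit interval, so images
are normalized on load and quantized back to 8 bits on save.

**Camera response (BTF).** Two exposures of one scene differing by ratio
`k` are related by `g(P, k) = exp(b(1 − kᵃ)) · Pᵏᵃ` with fixed parameters
`a = −0.3293`, `b = 1.1258` that fit typical consumer cameras; the same
curve is used for all three channels. The model satisfies an exact
composition law `g(g(P, k₁), k₂) = g(P, k₁k₂)` (up to output clamping),
which the tests exploit: darkening a scene by `k₀ < 1` and re-exposing by
`1/k₀` restores it exactly.

**Exposure search.** The optimal ratio maximizes the Shannon entropy of
the brightened luminance. Luminance is the per-pixel channel maximum by
default (consistent with the max-RGB illumination estimate; per-channel
mean is a config switch), histogrammed into 256 uniform bins on `[0, 1]`.
The image is resized to 50×50 (bilinear) for the search. Entropy rises
then falls with exposure but strict unimodality is not guaranteed on a
discrete histogram, so a 20-point log-spaced grid over `k ∈ [1, 10]`
locates the peak and a bounded scalar minimization refines it; the
reported optimum is never below any grid evaluation. The interval starts
at 1 because the method only brightens — well-exposed pixels are
preserved by the fusion, not by darkening. A constant image has flat
zero entropy; the search warns and returns `k = 1`.

**Illumination refinement.** The initial map is `T̂(x) = max_c P_c(x)`,
floored at `ε_T = 1e−3` wherever it later divides or blends. Gradient
weights per direction `d ∈ {h, v}` are

    W_d(x) = 1 / ( | Σ_{y∈Ω(x)} Ĝ(x, y) ∇_d T̂(y) | + ε ),

where `Ĝ` is a Gaussian of scale `σ = 2` px over a 5×5 window,
renormalized per pixel over the window∩image intersection. The
renormalization makes the numerator exactly 1 everywhere — including at
boundaries — so a constant map yields `W = 1/ε` uniformly and the
zero-gradient limit is exact; it is the package's boundary convention,
mirrored by the brute-force oracle in the tests. A distinct numerator
bandwidth is exposed (`sigma_numerator`) but defaults to `σ`.

The 1-norm smoothness term is relaxed to a quadratic with weights frozen
at `T̂`: `w̃_d(x) = W_d(x)/(|∇_d T̂(x)| + ε)`. The stationarity condition
is the SPD system `(I + α Σ_d D_dᵀ Diag(w̃_d) D_d) t = t̂` with `D_d` the
forward-difference operators (zero Neumann last row/column, column-major
vectorization) — identity plus a weighted graph Laplacian, hence always
solvable. Up to 1 Mpixel it is solved by sparse direct factorization;
above that by Jacobi-preconditioned conjugate gradients at tolerance
1e−6. `α = 0.15` balances fidelity and smoothing; all of `α, ε, σ`,
window radius are config-exposed since the weighting strategy is common
practice rather than a uniquely determined choice. The solution is
clamped to `[ε_T, 1]`.

**Fusion.** `W = T^μ` with `μ = 1` by default: the fusion weight must be
positively related to scene illumination and reduce to the refined map
itself in the natural case; the exponent allows softer blending. The
enhanced image is the convex combination `W∘P + (1−W)∘g(P, k̂)`, so the
output is always pixelwise between the two inputs. The gradient weight
matrices of the refinement play no role in fusion.

**Postprocessing.** Each channel is stretched between its 1% and 99%
intensity quantiles and shaped with gamma 0.9 (quantile rather than
min/max stretch mirrors the common intensity-adjustment routine with 1%
tail saturation; a constant channel passes through unchanged). Denoising
then runs on the Y channel (BT.601 full-range, chroma centered at zero)
of the stretched image: a two-stage block-matching collaborative filter
— groups of up to 16 mutually similar 8×8 blocks gathered within a
16-pixel search radius, a separable orthonormal 3-D transform (2-D DCT
per block, 1-D Haar along the stack), hard thresholding at `2.7σ` in the
first pass and empirical Wiener shrinkage driven by the first-pass
estimate in the second, aggregation with inverse-sparsity weights on a
stride-4 reference grid. The noise level `σ` is estimated from the
median absolute deviation of the finest diagonal detail when not
supplied. An external denoiser can be substituted through
`DenoiseParams.backend` without changing the contract. Raw and denoised
images are recombined as `R_f = R∘T + R_d∘(1−T)` — the refined, clamped
illumination map, not the fusion weight — so bright regions, whose noise
was barely amplified, stay crisp.

## Metrics

**LOE** counts, per reference pixel, how many pixel pairs flip their
relative lightness order between enhanced and reference image, using the
per-pixel channel maxima and the tie convention `U(p, q) = 1 iff p ≥ q`.
The double sum over all ordered pairs is normalized by the pixel count
`m`, so values range over `[0, m]`. Since the sum is quadratic in `m`,
images larger than the evaluation size (100 per side by default) are
nearest-neighbour downsampled first — nearest sampling cannot invent new
intensity orderings; images at or below that size are compared at full
resolution, which is what makes the small-image brute-force oracle exact.
Published LOE magnitudes (hundreds to thousands) are consistent with 1/m
normalization at roughly this evaluation resolution, but the original
evaluation resolution of the comparison literature is unstated, so
absolute published values are not reproducible; both the size and the
normalization are config-exposed.

**VIF** is implemented in the pixel domain with a scalar
Gaussian-scale-mixture observer rather than the wavelet-domain vector
GSM of the original formulation: deterministic, dependency-light, and it
preserves the two properties the evaluation relies on (self-fidelity of
exactly 1, monotone degradation with noise). Luminance on the 0–255
scale is analyzed at four dyadic scales (Gaussian blur + 2× decimation
between scales; scales smaller than 4 px are skipped). Local moments
under an 9×9 normalized Gaussian window (`σ = 1.5`, symmetric boundary)
give the reference variance `σ_C²` and the gain/noise decomposition
`(g, σ_V²)` of the distorted image, accumulated as

    VIF = Σ log₂(1 + g²σ_C²/(σ_V² + σ_N²)) / Σ log₂(1 + σ_C²/σ_N²),

with visual-noise variance `σ_N² = 2`. Windows whose reference variance
is below 1e−10 carry no information and are excluded from both sums —
this is what makes `VIF(x, x) = 1` exact; a reference with no variance
anywhere raises an error (fidelity undefined).

## Synthetic fixtures

`synthdata` generates deterministic (clean, degraded) pairs so every
stage is testable without image downloads. Scenes (`gradient`,
`checkerboard`, `blobs`, `mixed`) combine ramps, two-level boards,
Gaussian bumps and a hard step edge; each is brought to its
entropy-optimal exposure through the camera model itself (scenes with
exposure-invariant entropy, such as two-level boards, are left as built)
and affinely stretched to span `[0.02, 0.98]`. This makes "well-exposed"
mean the same thing to the generator and the enhancer — luminance
entropy peaks at unit exposure ratio — giving the exposure search an
exact ground truth of `1/dark_k` via the composition law.

Degradation applies an optional radial vignette (corners at 0.3×,
emulating nonuniform lighting), the BTF at `dark_k`, and seeded additive
Gaussian noise. Defaults: 128×128 `mixed` scene, `dark_k = 0.33` (about
a third of proper exposure), `noise_sigma = 0.01` (~2.5 digital numbers
of 8-bit read noise). All randomness flows from the single spec seed; an
identical spec is bit-identical.

What the fixtures do *not* emulate: demosaicing artifacts, compression,
spatially varying or signal-dependent (Poisson) noise, motion blur, and
real scene statistics. Passing tests therefore demonstrate the
pipeline's internal consistency and its behavior under its own camera
model, not photographic performance on natural images.

## Numerical choices and degenerate inputs

- Internal range `[0, 1]`; `ε_T = 1e−3` floors illumination maps used as
  divisors or blend weights.
- Histogram: 256 bins, last bin right-closed; entropy of an empty bin is 0.
- Refinement: forward differences with zero last row/column, used
  identically in `gradients` and in the operator matrices so the dense
  oracle equivalence is exact; `α = 0` short-circuits to `T̂`.
- Denoiser: `σ = 0` and constant-clean inputs are exact no-ops; planes
  smaller than one block pass through unchanged; group sizes are rounded
  down to powers of two for the Haar stack.
- Ties in LOE follow `p ≥ q` exactly.
- The whole enhancement path contains no random state; two runs on the
  same input and config are bit-identical.

## Problem sizes

Tests and the acceptance script run on 128×128 fixtures (a size at which
every stage, including both denoising passes, completes in about two
seconds), with oracle comparisons on maps up to 12×12 where dense
enumeration is exact. Larger images scale linearly in the denoiser and
near-linearly in the sparse solve.

## Known limitations

- The exposure search assumes the entropy-vs-exposure curve is
  effectively unimodal on the grid scale; pathological histograms could
  defeat the bracket.
- Fixed fusion exponent and fixed camera parameters: scenes shot with
  strongly non-standard response curves would need recalibration, which
  is out of scope.
- The simplified collaborative filter trades a few tenths of a dB
  against reference implementations for zero external dependencies; the
  backend hook exists for users who need the full variant.
- Absolute published LOE/VIF figures from the comparison literature are
  not reproducible here because the test photographs and the LOE
  evaluation resolution are not distributed; the package's metrics are
  validated by their identities and oracle equivalences instead.
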