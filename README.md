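# lumifuse

Low-light image enhancement for scientific and medical imaging, built
around an illumination-map-guided dual-exposure fusion pipeline, together
with the two objective quality metrics used to judge it (LOE and VIF).

Low-light captures — endoscopy frames, microscopy at short integration
times, surveillance-grade clinical photographs — are hard to read: detail
is buried in the dark regions, and naive brightening either blows out the
well-exposed regions or amplifies noise. `lumifuse` enhances such images
by synthesizing the well-exposed photograph the camera *would* have taken
at a longer exposure and blending it with the original only where it is
needed.

## The method

For an input image `P` the enhanced result is the per-pixel convex blend

    R_c = W ∘ P_c + (1 − W) ∘ g(P_c, k̂),      c ∈ {R, G, B}

where `g` is the camera's brightness transfer function (BTF)

    g(P, k) = exp(b (1 − kᵃ)) · P^(kᵃ),        a = −0.3293, b = 1.1258

relating the same scene at two exposures differing by ratio `k`. The
pieces are:

1. **Exposure sampler** — the ratio `k̂ = argmax_k H(g(B, k))` that
   maximizes the Shannon entropy of the brightened luminance `B`
   (entropy rises then falls with exposure; the search runs on a 50×50
   downsampled luminance over a bounded interval).
2. **Illumination map** — Retinex-style: `T̂(x) = max_c P_c(x)`, refined by

       min_T ‖T̂ − T‖²_F + α ‖W ∘ ∇T‖₁

   with Gaussian-windowed gradient weights that are small across genuine
   structure edges. The 1-norm is relaxed to a fixed-weight quadratic,
   reducing refinement to one sparse SPD linear solve.
3. **Fusion weight** — `W = T^μ`: well-lit pixels keep the original,
   underexposed pixels draw on the synthesized exposure.
4. **Postprocessing** — quantile range stretch with gamma 0.9, then a
   two-stage block-matching collaborative filter (hard-threshold pass,
   Wiener pass) on the Y channel only, recombined as
   `R_f = R ∘ T + R_d ∘ (1 − T)` so bright regions are never
   over-smoothed.

Quality is reported as **LOE** (lightness order error — the per-pixel
count of pixel pairs whose relative lightness ordering flips, lower is
better) and **VIF** (visual information fidelity — mutual information
extracted from the distorted vs. the reference image under a Gaussian
scale-mixture observer, 1 means perfect fidelity).

## Worked example

The synthetic-fixture module emulates a low-light capture by darkening a
well-exposed procedural scene through the pipeline's own camera model
(exposure ratio 0.33) and adding sensor noise:

```python
import lumifuse as lf

spec = lf.FixtureSpec(seed=7, scene="mixed", size=128, dark_k=0.33, noise_sigma=0.01)
clean = lf.make_scene(spec)
dark = lf.degrade(clean, spec)

enhanced, manifest = lf.enhance(dark)
print(f"k_hat          = {manifest['k_hat']:.3f}")
print(f"mean luminance = {manifest['mean_luminance_in']:.3f} -> {manifest['mean_luminance_out']:.3f}")
print(f"VIF vs clean   = {lf.visual_information_fidelity(dark, clean):.3f} (degraded) -> "
      f"{lf.visual_information_fidelity(enhanced, clean):.3f} (enhanced)")
print(f"LOE vs input   = {lf.lightness_order_error(enhanced, dark):.1f}")
```

prints

```
k_hat          = 3.169  (true inverse darkening 1/0.33 = 3.030)
mean luminance = 0.252 -> 0.596
VIF vs clean   = 0.622 (degraded) -> 0.928 (enhanced)
LOE vs input   = 547.8
```

The entropy search recovers the inverse of the applied darkening to
within 5%; enhancement raises the mean luminance back toward the clean
scene and recovers most of the visual information the darkening
destroyed, while the LOE stays in the range characteristic of
order-preserving enhancement at the default 100×100 evaluation
resolution.

The same flow is available from the shell:

```sh
lumifuse fixtures --seed 7 --size 128 --dark-k 0.33 -o fix/
lumifuse enhance -i fix/degraded.png -o enhanced.png --manifest run.json
lumifuse evaluate -e enhanced.png -r fix/clean.png
```

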