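# waveden

Edge-preserving denoising for single-channel medical images (e.g. B-mode
breast ultrasound), built from two classical stages and one modern tuning
loop:

1. **Wavelet shrinkage** — a 5-level Daubechies-2 (db2) decomposition with
   per-band **BayesShrink** soft thresholds
   `T_b = σ̂_n² / σ̂_x,b`, where `σ̂_n = median(|d₁ᴰ|)/0.6745` is the noise
   scale read off the finest diagonal band and
   `σ̂_x,b = sqrt(max(E[w²] − σ̂_n², 0))` the band's signal deviation.
2. **Bilateral post-filtering** — the exact window sum
   `I_B(x,y) = W_P⁻¹ Σ I(x′,y′) · exp(−Δ²/(2σ_s²)) · exp(−(ΔI)²/(2σ_r²))`
   over a `d × d` neighborhood, which smooths residual noise while weights
   collapse across intensity edges, preserving them.
3. **Bayesian optimization** of the bilateral triple `(d, σ_color, σ_space)`:
   a Gaussian-process surrogate over the search box, an
   expected-improvement acquisition
   `EI = (f* − μ)Φ(z) + σφ(z)`, `z = (f* − μ)/σ`, and the objective
   `f = −PSNR(clean, filtered)` so that minimizing `f` maximizes fidelity.

Because clean references rarely exist per image in practice, the package
also supports **parameter transfer**: tune once against a single reference
image, then apply the incumbent triple to every other image.

A synthetic-data module generates ultrasound-like phantoms (dark
background, bright fan-shaped sector, elliptical lesions) and the two
standard corruption models — additive Gaussian noise (mean 0, std 25 on the
8-bit scale) and Poisson noise whose per-pixel mean equals the pixel
intensity in counts — so the whole method is testable without any external
dataset. PSNR, MSE and SSIM (global or local-window) quality metrics are
included; all metrics use the unit [0, 1] working range with MAX = 1.

## Worked example

```python
from waveden import (NoiseSpec, PipelineConfig, add_gaussian_noise,
                     compare_methods, make_phantom)

clean = make_phantom(128, 128, n_lesions=3, seed=11)
noisy = add_gaussian_noise(clean, NoiseSpec("gaussian", gaussian_std=25.0, seed=1))
cfg = PipelineConfig(iterations=25, n_initial=10, seed=0)
for row in compare_methods(clean, noisy, cfg):
    print(f"{row['method']:>14}: PSNR {row['psnr_db']:6.2f} dB  "
          f"MSE {row['mse']:.6f}  SSIM {row['ssim']:.4f}")
```

prints

```
         noisy: PSNR  20.55 dB  MSE 0.008812  SSIM 0.8703
  wavelet_only: PSNR  32.33 dB  MSE 0.000584  SSIM 0.9901
bilateral_only: PSNR  22.81 dB  MSE 0.005242  SSIM 0.9188
      pipeline: PSNR  34.61 dB  MSE 0.000346  SSIM 0.9941
```

The noisy row is the corrupted input; wavelet-only removes most of the
noise (+11.8 dB); the full pipeline's tuned bilateral post-filter adds a
further +2.3 dB while raising structural similarity, the ordering the
method is built to produce. (The bilateral-only row applies the
pipeline-tuned triple directly to the raw noisy image.)

More walkthroughs live in `examples/` — phantom generation and the two
noise models, wavelet shrinkage internals, bilateral parameter sweeps, the
optimization loop, and parameter transfer. Each is a short script that
prints what it computes.

There is also a thin CLI:

```sh
waveden simulate --height 128 --width 128 --lesions 3 --noise gaussian \
        --std 25 --seed 11 --out noisy.png --clean clean.png
waveden optimize --clean clean.png --noisy noisy.png \
        --iterations 25 --seed 0 --out trace.json --denoised out.png
waveden evaluate --ref clean.png --test out.png
```

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter with units and defaults, the numerical conventions (boundary
handling, even-diameter windows, SSIM variants), and known limitations.
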