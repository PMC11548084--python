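# Methods

## The model

The package treats a degraded medical image as `I = I₀ + n`, with `I₀`
piecewise smooth and `n` either additive Gaussian noise or Poisson shot
noise. Restoration is a fixed two-stage composition:

1. **Wavelet BayesShrink.** The image is decomposed with an orthogonal db2
   basis over 5 levels. Under an additive-Gaussian model, detail
   coefficients are signal plus i.i.d. noise of standard deviation σ_n,
   estimated robustly from the finest diagonal band as
   `σ̂_n = median(|d₁ᴰ|)/0.6745` (that band is essentially pure noise for
   piecewise-smooth content). Each detail band `b` is soft-thresholded at
   `T_b = σ̂_n²/σ̂_x,b` with `σ̂_x,b² = max(E[w²] − σ̂_n², 0)` — the
   near-optimal soft threshold under a generalized-Gaussian coefficient
   prior. A band whose energy does not exceed the noise floor is
   annihilated (`T_b = max|w|`). The approximation band is never touched:
   thresholding it would shift mean intensity. The same σ̂_n is reused for
   every band (per-band quantities are the *signal* variances); soft
   rather than hard thresholding avoids spurious oscillations.
2. **Bilateral post-filter.** Shrinkage leaves low-amplitude residual
   noise and mild ringing near edges. The bilateral filter averages each
   pixel over a `d × d` window with weights
   `exp(−spatial²/(2σ_space²)) · exp(−ΔI²/(2σ_color²))`, normalized to a
   convex combination. With `σ_color` below the local edge contrast the
   range term suppresses averaging across edges, so flats are smoothed and
   edges survive.
3. **Tuning.** The triple `(d, σ_color, σ_space)` interacts with image
   content and residual-noise level, so it is optimized per image by
   minimizing `−PSNR(clean, bilateral(wavelet_output))` with GP-based
   Bayesian optimization (details below). When no per-image clean
   reference exists, the triple tuned on one reference image is
   transferred unchanged to the remaining images.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `wavelet.basis_name` | — | `db2` | any orthogonal Daubechies basis is accepted |
| `wavelet.levels` | — | 5 | feasibility bound `floor(log2(min side)) + 2` |
| `wavelet.boundary_mode` | — | `symmetric` | half-sample mirror padding |
| `d` | px | tuned, 3–9 | window diameter; even d uses offsets −d/2 … d/2−1 |
| `sigma_color` | 8-bit intensity | tuned, 10–150 | range-kernel width; the working image is converted to [0,255] inside the filter so published 8-bit values apply to unit-range inputs directly |
| `sigma_space` | px | tuned, 1–15 | spatial-kernel width inside the window |
| `iterations` | evaluations | 100 | guided evaluations after initialization |
| `n_initial` | evaluations | 10 | Latin-hypercube space-filling start |
| SSIM `k1, k2` | — | 0.01, 0.03 | stabilizers `c = (k·MAX)²`, MAX = 1 |
| SSIM `window` | — | `global` | `local` = 7×7 uniform sliding window, averaged over the fully supported interior |

Metrics are computed on the unit range with MAX = 1: published MSE values
of order 1e-4 alongside ~30 dB PSNR satisfy `PSNR = 10·log10(1/MSE)` only
on that scale. Population (denominator-N) moments are used in SSIM. Both
SSIM variants are provided because printed index magnitudes alone cannot
distinguish them; `global` is the default as the formula's single-shot
form.

## The optimizer

* **Surrogate:** Gaussian process with a constant × anisotropic
  Matérn-5/2 kernel (per-dimension length scales) on the unit-cube-scaled
  search box, targets normalized, 1e-6 diagonal jitter (numerical only —
  the objective is deterministic), hyperparameters by marginal-likelihood
  maximization with one restart.
* **Acquisition:** expected improvement in minimization form,
  `EI = (f* − μ)Φ(z) + σφ(z)`; maximized over 2048 seeded uniform
  candidates. If EI vanishes everywhere, the highest-variance candidate is
  taken so exploration continues.
* **Mixed space:** `d` is continuous for the surrogate and rounded to an
  integer at evaluation time. Evaluated triples are cached, so a
  re-proposed duplicate costs no second filter run while still occupying
  its trace slot — the trace always has exactly `n_initial + iterations`
  entries and the incumbent sequence is non-increasing by construction.
* **Convergence:** a fixed evaluation budget (default 100 guided
  iterations) is the primary criterion, reproducible by seed; an optional
  early stop halts after 15 iterations without ≥ 1e-3 dB incumbent
  improvement.
* A perfect reconstruction (infinite PSNR) is recorded as −200 dB so the
  surrogate sees finite targets.

## Synthetic data

Phantoms emulate the *geometry* of B-mode ultrasound: dark background
(0.06), a bright fan-shaped sector opening downward with a smooth
attenuation-like depth falloff (0.62 → 0.37), and elliptical lesions with
±0.15–0.35 intensity offsets, lightly smoothed (Gaussian, σ = 1.2 px) so
boundaries are curved. They deliberately do **not** model multiplicative
Rayleigh speckle, attenuation shadows, or scanner post-processing, so
passing tests demonstrate the pipeline's behavior on piecewise-smooth
content under the two stated noise models — not clinical performance on
real ultrasound texture.

Noise defaults are the study conditions: Gaussian mean 0 / std 25 on the
8-bit scale, and Poisson with per-pixel mean equal to the intensity in
counts (peak-count parameter 255 for unit-range images, making the noise
strength explicit and testable). Noisy images are clipped to the declared
range, matching 8-bit storage of real datasets.

Default experiment scale in the test-suite and reproduction script is
128×128 phantoms with 25 guided iterations — small enough to run the full
study everywhere, large enough that band statistics and the
optimization landscape behave as on full-size images.

## Numerical conventions and degenerate inputs

* DWT boundary handling is half-sample symmetric padding (the de-facto
  standard for image shrinkage; avoids edge ringing). Reconstruction is
  exact to machine precision; coefficient energy is only approximately
  conserved under padding, so no energy identity is relied upon.
* Decomposition deeper than the image supports raises an error naming the
  maximum feasible level count.
* Bilateral windows: odd `d` is centred; even `d` spans offsets
  −d/2 … d/2−1 (one pixel further up/left), the truncation convention of
  widely used implementations. Borders are mirror-padded to the window
  radius, which keeps the normalization full and avoids darkened borders.
  The exact double sum is always used — no grid or separable
  approximations.
* σ̂_n = 0 (noise-free input) gives zero thresholds: wavelet denoising is
  then the identity, as it should be.
* `d = 1` makes the bilateral filter the exact identity on the 8-bit
  working scale.
* Constant images pass through every stage unchanged; SSIM of identical
  images is exactly 1; PSNR of identical images is reported as +inf.

## Design choices that were genuinely open

* **Search-space defaults** (d 3–9, σ_color 10–150, σ_space 1–15) bracket
  the operating range of the method on 8-bit medical images with margin;
  published optima for this method family fall inside it.
* **Whether the iteration budget counts initialization:** it does not;
  `n_initial` and `iterations` are separate, and the trace records both.
* **Bilateral-only comparison row** in `compare_methods` applies the
  pipeline-tuned triple directly to the noisy image rather than re-tuning
  for that variant; this keeps the comparison single-tuning and is noted
  here because the convention affects that row's numbers.
* **Parameter transfer across noise models** is permitted (reports flag
  it) — the triple is just numbers; whether it is appropriate is the
  caller's call.

## Known limitations

* The clean-reference fidelity of the tuned pipeline is bounded by the
  least-smoothing triple in the search space: on a noise-free input the
  optimizer converges to that corner and the output sits in the ~50–56 dB
  range on phantoms rather than approaching identity, because
  `σ_space = 1` in a 3×3 window still averages noticeably. Widening the
  space downward would trade this for a slower search of mostly useless
  parameters.
* BayesShrink assumes additive Gaussian noise; for Poisson noise it acts
  on the signal-dependent variance only approximately (no variance
  stabilization is applied). Empirically the pipeline still improves
  Poisson-corrupted phantoms by a wide margin.
* Per-band thresholds use the zero-mean second moment of each band; bands
  with strong structured content at coarse levels can be under-shrunk.
* The optimizer's objective requires a clean reference; blind (no-reference)
  tuning is intentionally unsupported — transfer from a reference image is
  the supported alternative.
* Grayscale only; colour inputs must be reduced to luminance before use
  (the PNG reader averages channels).
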