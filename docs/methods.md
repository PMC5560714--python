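# Methods

This note documents the models and numerical choices behind `speclai`: what
the synthetic canopy generator simulates (and deliberately does not), how
the SPA, MLR and PLSR stages are defined, and how models are scored.

## Synthetic canopy spectra

### Optical model

For a sample with leaf area index `L`, canopy gap fraction follows
Beer–Lambert:

    T(λ, L) = exp(−k(λ) · L)

and noiseless canopy reflectance is a two-endmember mixture of bare soil
and dense leaf:

    R(λ) = R_soil(λ) · T(λ, L) + R_leaf(λ) · (1 − T(λ, L)).

This is the simplest mechanism that reproduces spectral saturation: at the
default `extinction_k = 0.5` (a typical spherical leaf-angle value),
T(3) ≈ 0.22, so reflectance loses most of its sensitivity to LAI above
LAI ≈ 3 — the knee reported for real winter-wheat canopies — and the
sensitivity |∂R/∂L| at 677 nm at L = 6 is under 10 % of its value at
L = 0.5.

The endmembers are fixed smooth parametric curves (sums of sigmoids and
Gaussians). The leaf endmember has chlorophyll absorption minima near 450
and 677 nm, the green reflectance peak near 560 nm, a steep red edge
between ~690 and 760 nm onto a NIR plateau (> 0.3), and leaf-water features
near 970, 1120 and 1290 nm. The soil endmember rises monotonically through
the visible and NIR (dry calcareous soil) and declines beyond ~1100 nm
(soil moisture absorption); the decline is what gives the leaf-water
features usable soil–leaf contrast.

### Planted informative bands

Ten feature centers are planted as recoverable ground truth:
410, 450, 540, 677, 715, 735, 816, 970, 1120, 1290 nm. Two mechanisms make
them — and only them — carry band-specific LAI information:

1. **Differential saturation.** The extinction coefficient is wavelength
   dependent, `k(λ) = extinction_k · m(λ)`, with `m ≡ 1` outside compactly
   supported ±10 nm windows around the centers. Strongly absorbed
   chlorophyll bands saturate faster (m up to 2.4 at 677 nm), red-edge /
   NIR / water bands slower (m down to ~0.3). Away from the feature
   windows every band is an affine function of one shared gap fraction, so
   after one band is selected the rest are redundant by construction.
2. **Absorber-concentration variability** (`feature_cv`, default 0.15).
   The chlorophyll, water and dry-matter content behind each feature varies
   between plots at a given LAI; each sample draws an independent relative
   jitter per feature that scales that feature's extinction inside its
   window. This is essential, not cosmetic: a single latent variable can
   feed only a handful of numerically distinguishable spectral directions
   (the singular values of the family {exp(−k·L)} over a field-realistic
   LAI population decay by roughly an order of magnitude per direction), so
   without per-feature variability no selection method could recover ten
   planted bands. With it, each feature window owns an independent variance
   direction while remaining deterministically linked to LAI.

### Population structure and noise

Per field type, LAI is drawn from a normal truncated to the observed range
(irrigated: mean 5.100, SD 2.283 on [1.31, 11.91]; rainfed: mean 2.951,
SD 2.002 on [0.31, 9.27]); sample counts default to 93 and 84. Growth-stage
labels (jointing/booting/filling) are assigned by LAI tercile and carried as
metadata only. Irrigated and rainfed fields share identical optics — they
differ only in the LAI distribution, which is what isolates the saturation
effect.

Each sample is scanned `n_replicates = 3` times; each scan is
`R·(1+ε_m) + ε_a` with ε_m ~ N(0, 0.01²), ε_a ~ N(0, 0.005²) (multiplicative
1 %, additive 0.005 reflectance), clipped to [0, 1]. Replicates are averaged
per band before analysis.

Between-plot heterogeneity, all canopy-structural rather than instrumental:

| parameter | default | meaning |
|---|---|---|
| `extinction_cv` | 0.32 | global extinction jitter: leaf-angle/variety/stage architecture acting coherently over the whole spectrum |
| `soil_brightness_cv` | 0.10 | per-plot soil background brightness |
| `feature_cv` | 0.15 | per-feature absorber concentration (see above) |

The coherent `extinction_cv` term is the dominant, irreducible part of the
LAI error budget (a coherent spectral rescaling is indistinguishable from a
rescaled LAI, so no band combination can remove it; its error contribution
grows with LAI, which is also what drives the irrigated field's poorer
models). The defaults were calibrated once so that the default conditions
put the 10-band SPA-MLR validation model in the *moderate* RPD class
(1.4–2), i.e. at a field-campaign level of accuracy rather than a
simulation-perfect one; instrument noise alone is far too benign for that
because replicate averaging and multi-band regression suppress it.
`SimulationConfig.low_noise()` gives the idealised variant (noise ≈ 0,
homogeneous architecture and soil, biological `feature_cv` retained) used
to verify parameter recovery.

What the generator does **not** emulate: bidirectional reflectance and
sun-angle effects, growth-stage spectral dynamics, instrument spectral
response (the 1.4/2 nm ASD sampling intervals — an optional linear
regridder handles such exports), and any physically rigorous radiative
transfer (no PROSAIL). Passing tests therefore demonstrate the correctness
and statistical behaviour of the *pipeline*, not the realism of canopy
physics.

## Preprocessing

* **Replicate averaging**: per-band arithmetic mean of the replicate scans.
* **Savitzky–Golay smoothing**: window 9 points, polynomial order 2,
  along wavelength. Field protocols often quote an "8-point" smooth; a
  Savitzky–Golay window must be odd, so the nearest odd width (9) is used,
  and order 2 is common chemometric practice. Edges are handled by fitting
  the order-2 polynomial to the one-sided window of the first/last 9
  samples (no padding is invented beyond the signal). The filter is linear
  with unit DC gain and reproduces polynomials up to the filter order
  exactly.
* **Band subsetting**: the analysis range is the closed interval
  [400, 1400] nm (1001 bands at 1 nm).

## Ground-truth LAI

From a 1 m² quadrat: all leaves weighed (`w1`), five cut leaf segments of
measured area `s1` weighed (`w2`). Total leaf area is the weight-
proportional scale-up `S = s1 · w1 / w2` and `LAI = S / ground_area` after
cm²→m² conversion. Field write-ups of this protocol are sometimes
ambiguous; two alternative readings (`s1·(w1+w2)/w1`, `s1·(w1+w2)/w2`) are
selectable via a formula-variant flag for auditability, with the
dimensionally coherent default above.

## SPA band selection

Calibration columns are mean-centered (no autoscaling — the usual
chemometric default for reflectance; an autoscale flag is deliberately
absent since the pipeline never needed it). A chain from start band `s` is
grown by projection deflation: every remaining column is deflated against
the last-selected (deflated) column, and the column with the largest
residual norm is appended; exact ties break to the lowest band index for
determinism. Sequential deflation is algebraically identical to
orthogonalising against the span of the whole selected set (verified
against a dense Gram–Schmidt oracle). A candidate whose residual norm
vanishes relative to the matrix scale (tolerance 1e−10) signals a
duplicate/degenerate band and raises rather than being silently skipped.

Every start band and every subset size m in the configured range is scored
by the validation RMSE of an MLR model fit on the calibration samples
restricted to the chain's first m bands; the best (start, m) wins, with
ties to smaller m then smaller start. Default usage fixes m = 10. The
scoring set is the held-out validation split of the main 2:1 split — the
standard SPA formulation; note this means validation metrics of the
SPA-MLR model are not fully independent of selection, which mirrors common
practice in field studies. SPA's optional relevance-based elimination
phase is not implemented.

## Regression models

* **MLR**: ordinary least squares with intercept (`numpy.linalg.lstsq`);
  rank deficiency and under-determination raise instead of silently
  regularising.
* **PLSR**: univariate-response NIPALS on mean-centered data. Per factor:
  w = X'y/‖X'y‖, t = Xw, p = X't/t't, q = y't/t't, deflation X ← X − tp',
  y ← y − tq. Scores are mutually orthogonal (checked to 1e−8) and the
  deflation conserves Frobenius energy. Factors fold back into per-band
  B-coefficients b = W(P'W)⁻¹q with intercept ȳ − x̄·b, so a PLSR model
  predicts exactly like a linear model.
* **Factor selection**: leave-one-out RMSECV over 1..max_factors (default
  cap 12), refitting the decomposition on every fold; ties in the argmin go
  to the smaller count (parsimony). If a fold's covariance is exhausted
  before max_factors, the prediction curve is flat beyond the achieved
  rank — extra factors contribute nothing rather than erroring.
* **VIP**: VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) with
  SS_a = q_a²·t_a't_a (the response variance captured by factor a — the
  standard Wold weighting). Mean squared VIP is exactly 1; the screening
  threshold is VIP > 0.8.
* **Correlation curve**: per-band Pearson correlation with LAI; exactly
  zero-variance bands are flagged (NaN + index list), never silently set to
  0; local extrema of |r| are located over a ±5-band window.

## Evaluation

The 2:1 calibration/validation split assigns round(2n/3) samples to
calibration (93 → 62/31, 84 → 56/28), uniformly at random, deterministic
per seed. Metrics:

* RMSE = sqrt(mean squared error), in LAI units.
* R² = squared Pearson correlation of observed vs predicted (the 1:1-plot
  convention); a 1 − SSE/SST variant is available behind a flag.
* RPD = SD(observed, n−1 denominator) / RMSE. Classes: > 2 good, 1.4–2
  moderate (closed interval on both boundaries), < 1.4 poor. A zero RMSE is
  reported as a degenerate-perfect error rather than an infinite RPD.

For an in-sample least-squares fit, RPD ≈ 1/√(1−R²) up to the n/(n−1)
factor; the test suite checks this near-identity to 5 %.

## Pipeline

Each field type is an independent run: simulate (or read) → average →
smooth → subset → split → correlation curve → SPA-MLR → full-spectrum PLSR
(LOO factors, VIP, B-coefficients) → reports. One global seed drives a
named per-stage seed sequence (LAI draw, structure, noise, split), so any
stage reproduces in isolation and a manifest (config hash + seed +
versions) makes every numeric output bit-reproducible. No pooled
(field-agnostic) model is fit: separating field types is the point of the
design. All artifacts are plain CSV/JSON.

## Problem sizes

Default runs use the full study geometry (93 + 84 samples, 1001 bands,
all 1001 SPA starts; a full two-field run takes a few seconds). The test
suite exercises stochastic properties at 20 seeds with the same geometry,
and unit tests use reduced grids (5–10 nm steps, ~30 samples) chosen to
keep the suite fast while preserving every structural property.

## Known limitations

* The generator's realism is limited to what the pipeline's statistics
  need (see above); absolute reflectance values are plausible but not
  instrument-calibrated.
* SPA scoring on the shared validation split mildly optimistic-biases the
  SPA-MLR validation metrics (documented above, standard in the field).
* RPD class boundaries are conventions; values within ±0.05 of a boundary
  should not be over-interpreted.
* The LOO factor cap (12) is a compute/stability trade-off; raising it is
  a one-line config change.
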