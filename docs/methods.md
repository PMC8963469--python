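# Methods

This note documents the models, numerical choices and known limitations
behind `hyperspad`. It is written for a maintainer or reviewer who wants
to know *why* the pipeline behaves the way it does, not just what it
computes.

## Problem setting

The package retrieves a leaf-chlorophyll proxy — SPAD units, the
unitless transmittance-ratio reading of a handheld chlorophyll meter —
from hyperspectral reflectance, across a multi-campaign crop season.
The retrieval chain is: leaf spectra and SPAD ground truth per campaign
→ spectral preprocessing → predictor assembly (272 bands, the 145 bands
used by the index registry, or 60 vegetation indices) → a roster of 17
regression models trained under two temporal strategies → accuracy-based
model selection → per-pixel SPAD maps with uncertainty → per-plant
averages on the sowing grid.

## Synthetic field data

Real multi-campaign field data of this kind is rarely public, so every
stage is driven by a seeded generator whose defaults encode the study
conditions the pipeline targets: five campaigns of 108 leaflet samples
(75 in the last, after plant losses), SPAD box-plot summaries rising
from a median of 33 to 55 across the season, green-peak reflectance
near 18% falling to ~15%, and a NIR plateau near 0.45–0.56.

**SPAD law.** Campaign SPAD values are drawn by inverse-CDF from the
piecewise-linear quantile function through the five-number summary
(min, Q1, median, Q3, max). A bounded parametric family (e.g. a scaled
Beta) was considered and rejected: its density vanishes at the support
endpoints, so sample minima/maxima cannot match box-plot whiskers at
any realistic n, while the quantile law matches all five numbers by
construction. Whisker values not available per campaign were fixed once
at plausible levels consistent with the described distribution shapes.

**Leaf spectra.** Reflectance on the 1-nm 400–1,000 nm grid follows a
Beer–Lambert-style attenuation of a smooth baseline:

    R(λ) = f + [A_vis (1 − L(λ)) + P·L(λ) − f] · exp(−k(λ) · c(SPAD))

with `L` a logistic red-edge transition (inflection 710 nm, scale
18 nm), `P` the per-sample NIR plateau, `A_vis = 0.191` the pigment-free
visible level, `f = 0.03` a residual surface reflectance that no pigment
absorption removes (real leaves never reach zero at 680 nm; without it,
ratio indices and continuum removal degenerate), and `k` a sum of
Gaussian absorbers for Chl-a (430, 680 nm), Chl-b (460, 650 nm) plus a
broad green term. The chlorophyll link `c(SPAD) = exp(SPAD/25) − 1` is
exponential, consistent with the mostly exponential SPAD-to-chlorophyll
relations reported across species. `A_vis` and the green absorber
strength were calibrated once so that the campaign-1 ensemble mean
spectrum peaks at 0.18 in the green with the stated SPAD distribution;
the later campaigns' ~0.15 green peaks then emerge from their higher
SPAD medians without per-campaign re-calibration.

Two error sources are modeled deliberately:

* additive per-wavelength spectral noise (sd 0.004 reflectance) plus
  per-sample jitter of the visible level and NIR plateau matching the
  campaign green/NIR standard deviations;
* SPAD observation error (sd 1.5 units, clipped to the meter's [0, 70]
  range): meters carry ±1 unit instrumental accuracy and
  environmental biases of a few units — the same error budget that
  motivates the 5-unit model-selection threshold. Without this term the
  synthetic retrieval problem is unrealistically clean (validation RMSE
  ~1.4 versus the 2–5.5 range typical of field studies).

**Campaign drift.** Each campaign can scale the chlorophyll link
multiplicatively (defaults between −10% and +12%, zero in campaign 1).
This makes the SPAD→spectrum mapping non-stationary across the season —
the situation cumulative retraining is designed to exploit. `drift=False`
produces the stationary control.

**Cubes.** A mini field (default 12×5 plants, 3×3 pixels per plant,
1-pixel soil border, 0.007 m pixels) embeds per-plant spectra resampled
to the 272-band grid into a soil background, with six flat gray panels
(reflectance 0.03–0.56) in a bottom strip and an exact plant/soil mask.
Radiance mode divides by known per-band gains and subtracts offsets so
the empirical-line fit can be validated by round trip. The generator
does not attempt radiative-transfer realism: no canopy BRDF, no shadows
beyond a brightness jitter, no mixed pixels.

## Preprocessing

* **Gaussian resampling** uses per-band Gaussian spectral response
  functions with σ = FWHM/2.3548, truncated at ±3σ and clipped
  symmetrically at the input edges. Because the input grid points are
  not exactly symmetric about a band center, raw Gaussian weights would
  bias linear spectra by ~2×10⁻⁴ near the edges; the weights therefore
  receive a first-moment correction (rescaling by α + βΔλ) making
  constants and linear ramps exact at every band. Inputs extending
  beyond 400–1,000 nm (full-range field spectrometers) are cropped
  first.
* **Empirical line**: per-band least-squares affine fit from ≥2 panels;
  degenerate (constant-radiance) bands raise an error naming the band.
  Application clips to [0, 1] and counts clipped values.
* **Savitzky–Golay**: default window 11 bands, polyorder 2 (the source
  workflow does not state values; these are common practice and
  configurable). Edges use local polynomial interpolation rather than
  mirror padding so polynomials of degree ≤ 2 are exact fixed points.
* **MNF**: noise covariance from horizontal 1-pixel shift differences
  (inside the plant mask when given), noise-whitening, eigendecomposition
  of the whitened signal covariance, truncation, inversion. With
  `k=None` components with whitened eigenvalue > 1 are kept. A singular
  noise estimate (e.g. duplicate pixels) is ridge-regularized with a
  warning, which makes such cubes fixed points of the transform.

## The index registry

Sixty indices in nine groups: broadband greenness (5), narrowband
greenness (7), light-use efficiency (3), senescence (2),
stress-on-pigments (4), water content (2), reflectance-based leaf
chlorophyll (15), derivative-based leaf chlorophyll (16),
continuum-removed (6). About half carry names fixed by the application
literature (NDVI, SRI, PRI, SIPI, PSRI, CRI1/2, ARI1/2, WBI, MTVI2,
TCARI, MCARI, MCARI/OSAVI, GNDVI, NDCI variants, Datt, the Vogelmann
and four-point red-edge indices, D720, DSR1, EGFN, DPI, FDNDVI, ANMB,
AUC, LPSDI, SAVI, …); the remaining slots are filled from the same
cited source families and are flagged by their citation keys as
reconstructions.

Numerical conventions, applied uniformly:

* **Nearest-band snapping**, no interpolation, for formula wavelengths —
  matching discrete-band instrument practice. Where a source admits
  wavelength variants, the variant was chosen so that the registry's
  unique snapped band union on the 272-band grid is exactly 145 bands;
  each choice is recorded in the citation field.
* **Derivatives** are Savitzky–Golay first derivatives over a fixed
  ~25 nm physical window (11 bands on the camera grid, 25 points on the
  1-nm grid), in per-nm units, so derivative indices are comparable
  across grids.
* **Continuum removal** divides by the upper convex hull (monotone-chain
  construction) over the index's window; band depth = 1 − CR.
* Non-finite results (division by zero, undefined red edge on a flat
  spectrum) are flagged by index name and returned as NaN, never
  silently dropped.

Each index declares two property classes that the test suite asserts:
`scale_invariant` (invariance under R → cR; true for pure ratio and
normalized-difference forms, false for forms with additive constants
such as SAVI/EVI or with unbalanced reciprocals such as CRI/ARI) and
`resample_robust`. The latter deserves a note: indices sampling steep
spectral slopes or reciprocal differences (the CRI/ARI family, Vogelmann
ratios, MCARI/TCARI, most derivative indices) change by more than a few
percent between the 1-nm and the 272-band evaluation of the same leaf,
because nearest-band snapping shifts the sampled wavelength by up to
1.1 nm and the 6 nm bandwidth alters steep-edge reflectance — at high
chlorophyll, 1/R(700) moves ~6% per 0.5 nm. This is a property of
discrete-band instruments, not of the implementation; those indices'
*ranking* of leaves by chlorophyll is preserved (rank correlation
~0.9–1.0 across a SPAD grid), which is what matters for their use as
regression predictors. The suite therefore asserts a 2% value band for
the 30 value-stable indices and rank stability for the rest.

## Learning harness

**Split.** Per campaign, samples are sorted by SPAD and dealt into
`round(0.2·n)` quantile blocks; one seeded draw per block goes to
validation. This yields 86/22 for a 108-sample campaign and keeps subset
distributions matched (medians within 0.5 units at large n).

**Roster (17).** Multivariate linear; PLSR (components tuned 1–15 by
5-fold CV RMSE); fine/medium/coarse decision trees (min leaf 4/12/36);
boosted and bagged (random forest) ensembles of 60 medium trees; SVR
linear/quadratic/cubic plus fine/medium/coarse Gaussian kernels (kernel
scale √p/4, √p, 4√p); GPR with exponential, squared-exponential,
Matérn-5/2 and rational-quadratic kernels (constant × kernel + white
noise, maximum-likelihood hyperparameters). Scaling-sensitive models
(SVR, GPR) run behind a standardizer. All stochastic learners are
seeded; a fixed seed reproduces every metric bit-for-bit.

**Strategies.** Sequential fits one model on all campaigns pooled.
Retraining fits one model per cumulative campaign prefix (t1, t1+t2, …)
with hyperparameters tuned on the first prefix and frozen; campaign i is
predicted by prefix-i model. With a single campaign the two strategies
coincide exactly (asserted bitwise in the suite).

**Metrics.** R² uses the conventional mean-anchored total sum of squares
(1 − SSE/SST); RMSE and MAE are the standard forms. R² on constant
targets raises rather than returning NaN.

**Selection.** Models pass if validation RMSE ≤ 5 *and* MAE ≤ 5 SPAD
units — the combined instrumental accuracy (±1) and environmental bias
(2–4 units) of the meter readings themselves; predicting more accurately
than the labels is not meaningful.

## Feature importance and consensus

PLSR relevance is the per-component weight matrix; the per-predictor
aggregate is the maximum |weight| across components ("relevant in any
component"; the alternative — variance-weighted averaging — buries
predictors that dominate a single later component). Random forest uses
normalized impurity importances. GPR relevance requires an ARD
(per-dimension) squared-exponential kernel — prediction runs may use
isotropic kernels, so importance runs refit with ARD on standardized
inputs; the fitted length scale is a *weakness* index (large scale =
weak predictor). The ARD marginal-likelihood optimization is capped at
15 L-BFGS iterations: ranking length scales does not need the optimum to
machine precision, and the cap keeps 20-dimensional fits at n=500 under
~3 s without changing the recovered ranking.

Each method's relevant set is the inclusive quartile rule — score ≥ Q3
(linear-interpolation quantile) for PLSR and RF, score ≤ Q1 for GPR
weakness; ties are kept, so the relevant set holds 25–100% of
predictors. Consensus counts how many methods flag each predictor (1–3).
For band predictors, contiguous relevant runs narrower than 10 nm are
reported as a single variable centered on the run.

## Mapping

Pixel predictions outside the meter's [0, 70] range become nodata gap
pixels (they are counted, not clipped — mirroring how negative
retrievals appear as gaps in published maps). GPR models add
σ₉₅ = 1.96 × predictive standard deviation, the half-width of the
central 95% interval of the Gaussian predictive law; the phrase
"standard deviation at 95% confidence" is ambiguous between the SD
itself and the interval half-width, and the half-width reading matches
the magnitudes typically discussed (the multiplier is a named constant
if the other reading is wanted). Plant averages are means over the
valid pixels of each plant's footprint; empty cells are nodata with a
count report. Mask conservation (masked = valid + flagged-invalid) and
aggregation consistency (count-weighted mean of cell means = global
pixel mean) are asserted invariants.

## Study-scale experiments (workflows)

* **Consensus recovery**: y = 2x₀ + ε with 19 noise predictors, n=500;
  the planted predictor must reach consensus count 3. 50 seeds.
* **Strategy experiment**: 20 seeded replicates of the five-campaign
  simulation, drift on and off, scoring per-campaign validation RMSE
  averaged over campaigns 3–5 (where the two strategies' training sets
  genuinely diverge). The roster member used is the GPR squared
  exponential: it is one of the two models the retraining strategy
  favors in this literature, and — unlike PLSR or random forest, whose
  accuracy at these sample sizes still improves appreciably between
  n≈260 and n≈430 — its error saturates by the prefix-3 training size,
  so the drift-off control isolates the strategy effect rather than the
  training-set-size effect.
* **Full workflow**: five campaigns at n=108/75, the full 17-model
  roster under both strategies on the 60-index predictor set, 5-unit
  selection, then per-campaign 12×5-plant mini cubes mapped with the
  best selected record (a retraining record maps campaign i with its
  prefix-i model, mirroring how production maps use each model under
  the strategy it performs best). Plant-cell means are compared with
  the latent per-plant SPAD against a 95% bound of
  1.96 × max(pooled, per-campaign) validation RMSE — the per-campaign
  term matters because under drift the mapping model's error is not
  homogeneous across campaigns, and its own validation breakdown
  already measures that. ≥95% of the 300 cells recover within the
  bound. Problem sizes (mini cube, 60-index predictor set for the
  roster sweep) were chosen to keep a full workstation run in the low
  minutes while exercising every stage.

## Known limitations

* The generator's spectra live on a one-dimensional latent axis (SPAD
  plus noise); real canopies add water/structure covariates, BRDF and
  illumination effects, so passing tests demonstrate pipeline
  correctness and the stated statistical properties, not field accuracy.
* The 145-band union depends on the documented wavelength-variant
  choices; a different variant table would shift it by a few bands.
* The drift model is a scalar multiplicative perturbation of the
  chlorophyll link; real non-stationarity (phenology, stress) is richer.
* GPR uncertainty is taken at face value from the Gaussian predictive
  law; no calibration of coverage is performed.
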