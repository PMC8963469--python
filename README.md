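# hyperspad

Multi-temporal retrieval of SPAD-based leaf chlorophyll from
hyperspectral reflectance.

## What problem this solves

Leaf chlorophyll drives photosynthesis, and agronomists track it
in-situ with SPAD chlorophyll meters — a unitless transmittance-ratio
reading (red 650 nm vs NIR 940 nm) that rises monotonically with leaf
chlorophyll content. Meter readings are accurate but pointwise:
covering a field of hundreds of plants across a growing season is
impractical. Hyperspectral cameras on drones can observe every plant at
sub-centimeter resolution, so a natural program is: train regression
models that map leaf reflectance (400–1,000 nm, 272 bands) to SPAD using
a modest set of ground-truth leaflets, then apply them per pixel to the
imagery to produce SPAD maps of the whole field, campaign after
campaign.

`hyperspad` implements that workflow as a tested, reusable Python
library for researchers in plant phenotyping and imaging spectroscopy:

- **`synth_field`** — a seeded generator emulating a five-campaign
  phenotyping study (SPAD box-plot distributions, Beer–Lambert-style
  leaf spectra with chlorophyll absorbers at 430/460/650/680 nm and a
  shifting red edge, mini field data-cubes with soil, calibration
  panels and a plant mask), so every downstream stage is testable
  without field data.
- **`spectral_io`** — ENVI-style cube reader/writer (BSQ/BIL/BIP) and
  CSV sample tables.
- **`preprocess`** — Gaussian spectral-response resampling onto the
  272-band grid, per-band empirical-line calibration from gray panels,
  Savitzky–Golay smoothing, minimum-noise-fraction denoising.
- **`indices`** — a registry of 60 pigment vegetation indices in nine
  groups (touching 145 unique bands), with the operators they need:
  nearest-band sampling, derivative spectra, convex-hull continuum
  removal, red-edge position.
- **`harness`** — distribution-matched 80/20 splitting, a roster of 17
  regression models (linear, PLSR, trees, ensembles, SVR and GPR
  variants), *sequential* (train once on everything) versus
  *retraining* (cumulatively refit per campaign) strategies, R²/RMSE/MAE
  scoring and the 5-SPAD-unit selection rule.
- **`importance`** — cross-model feature relevance (PLSR weights, RF
  importance, GPR ARD length scales), quartile classification and
  1/2/3-method consensus.
- **`mapping`** — per-pixel SPAD maps with gap-pixel handling, GPR
  σ₉₅ uncertainty layers, and per-plant averages on the sowing grid.
- **`workflows`** — the study-scale experiments wired end to end.

The scientific core in one line: given per-leaflet pairs (x, y) of
reflectance-derived predictors and SPAD readings, fit ŷ = f(x) by
cross-validated regression, judge each f by validation RMSE/MAE against
the ~5-unit error budget of the meter itself, and prefer cumulative
retraining over pooled training when the predictor–SPAD relationship
drifts across the season.

## Worked example

```python
import numpy as np
from hyperspad.synth_field import (default_campaigns, simulate_samples,
                                   simulate_cube, spad_quantile,
                                   FieldLayout, LeafSpectrumModel)
from hyperspad.preprocess import resample_table
from hyperspad.indices import default_registry
from hyperspad.harness import (split_dataset, make_dataset, default_roster,
                               fit_sequential, evaluate, select_models)
from hyperspad.mapping import predict_cube, plant_average
from hyperspad.spectral_io import SensorModel

sensor = SensorModel()                      # 272 bands, 400-1000 nm
registry = default_registry(sensor)         # 60 vegetation indices

# five synthetic campaigns (n=108, 108, 108, 108, 75), resampled
table = resample_table(simulate_samples(default_campaigns(), seed=11), sensor)
train, val = split_dataset(table, seed=11)  # 86/22 per 108-sample campaign
dtr = make_dataset(train, "vis", registry, sensor)
dva = make_dataset(val, "vis", registry, sensor)

cfg = {c.name: c for c in default_roster()}["GPRSquaredExponential"]
model = fit_sequential(cfg, dtr, seed=11)
record = evaluate(model, dva)
print(f"{record.model}: RMSE = {record.rmse:.2f}, MAE = {record.mae:.2f}")
kept, _ = select_models([record])           # 5-SPAD-unit rule
print("selected:", [r.model for r in kept])

# map a 12x5-plant mini cube and average per plant
layout = FieldLayout()
spec = default_campaigns()[2]
truth = spad_quantile(spec, np.random.default_rng(5).uniform(0, 1, (12, 5)))
scene = simulate_cube(layout, truth, LeafSpectrumModel(), spec, seed=5)
pmap = predict_cube(model, scene.cube, scene.mask, registry=registry)
means, sigma, counts = plant_average(pmap, layout, scene.plant_ids)
err = np.abs(means - truth)
print(f"plant cells within 1.96*RMSE: {np.mean(err <= 1.96*record.rmse):.0%}")
print(f"mean GPR sigma95: {np.nanmean(sigma):.1f} SPAD units")
```

Output:

```
GPRSquaredExponential: RMSE = 2.21, MAE = 1.83
selected: ['GPRSquaredExponential']
plant cells within 1.96*RMSE: 100%
mean GPR sigma95: 5.1 SPAD units
```

Read: the GPR with a squared-exponential kernel, trained on the
60-index predictor set, predicts held-out SPAD to ~2.2 units — well
inside the 5-unit error budget of the meter readings themselves, so it
passes selection. Applied per pixel to a simulated field cube and
averaged per plant, every plant's mean retrieval lands within the
model's 95% error bound of its true SPAD, and the GPR's own predictive
uncertainty (~5 units at 95%) is honest about the per-pixel noise.

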