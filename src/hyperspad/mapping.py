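"""Pixel-level SPAD maps and per-plant aggregation.

A selected fitted model is applied to every plant pixel of a cube
(either raw band spectra or a vegetation-index stack, matching the
model's predictor set).  Retrievals outside the chlorophyll meter's
operating range [0, 70] are treated as gap pixels (nodata), not
clipped, mirroring how negative retrievals appear as gaps in published
maps.  Probabilistic (GPR) models add an uncertainty layer:
sigma95 = 1.96 x predictive standard deviation, the half-width of the
central 95% interval under the Gaussian predictive law.

Plant-level summaries average the valid pixels inside each plant's
footprint into the rows x columns sowing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import HyperspadError
from .harness import FittedModel
from .indices import IndexDefinition, compute_matrix
from .spectral_io import ReflectanceCube
from .synth_field import FieldLayout

__all__ = [
    "PredictionMap",
    "predict_cube",
    "sigma95",
    "plant_average",
    "SPAD_VALID_RANGE",
]

#: Chlorophyll-meter operating range; retrievals outside become nodata.
SPAD_VALID_RANGE = (0.0, 70.0)

Z95 = 1.96  # central 95% half-width multiplier for a Gaussian


@dataclass
class PredictionMap:
    """SPAD raster plus optional uncertainty and full provenance."""

    spad: np.ndarray                  # float, NaN = nodata
    sigma95: np.ndarray | None
    valid: np.ndarray                 # bool, predicted and in range
    n_masked: int                     # pixels the mask let through
    n_invalid: int                    # predictions flagged out of range
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma95 is not None and np.any(
                self.sigma95[np.isfinite(self.sigma95)] < 0):
            raise HyperspadError("sigma95 must be non-negative")
        if self.n_masked != int(self.valid.sum()) + self.n_invalid:
            raise HyperspadError(
                "mask conservation violated: masked != valid + invalid"
            )


def sigma95(model: FittedModel, x: np.ndarray) -> np.ndarray:
    """Half-width of the 95% predictive interval, in SPAD units."""
    return Z95 * model.predict_std(np.atleast_2d(x))


def predict_cube(model: FittedModel, cube: ReflectanceCube,
                 mask: np.ndarray,
                 registry: list[IndexDefinition] | None = None,
                 campaign: str | None = None) -> PredictionMap:
    """Apply a fitted model to every masked-in pixel of a cube.

    The cube must be on the model's native grid; for a ``vis`` model the
    index registry evaluates the predictors per pixel, for
    ``selected_bands`` the registry's unique wavelengths subset the band
    axis.  Out-of-range retrievals become nodata and are counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cube.lines, cube.samples):
        raise HyperspadError("mask geometry does not match the cube")
    flat = cube.data.reshape(-1, cube.bands).astype(float)
    sel = mask.reshape(-1)
    pixels = flat[sel]

    pset = model.predictor_set
    if pset == "all_bands":
        x = pixels
    elif pset == "selected_bands":
        if registry is None:
            raise HyperspadError("selected_bands mapping needs the registry")
        from .indices import registry_wavelengths

        wl = registry_wavelengths(registry, cube.sensor)
        cols = [cube.sensor.nearest_band(w) for w in wl]
        x = pixels[:, cols]
    elif pset == "vis":
        if registry is None:
            raise HyperspadError("vis mapping needs the registry")
        x = compute_matrix(registry, pixels, cube.sensor.band_centers)
    else:
        raise HyperspadError(f"unknown predictor set {pset!r}")

    n_model = getattr(model.estimator, "n_features_in_", None)
    if n_model is None and hasattr(model.estimator, "named_steps"):
        n_model = model.estimator.named_steps["model"].n_features_in_
    if n_model is not None and x.shape[1] != n_model:
        raise HyperspadError(
            f"predictor-set mismatch: cube yields {x.shape[1]} features "
            f"({pset}), model {model.name} was fitted on {n_model}"
        )

    y = model.predict(x)
    lo, hi = SPAD_VALID_RANGE
    finite = np.isfinite(y)
    in_range = finite & (y >= lo) & (y <= hi)
    n_invalid = int((~in_range).sum())

    spad = np.full(cube.lines * cube.samples, np.nan)
    spad[np.nonzero(sel)[0][in_range]] = y[in_range]
    spad = spad.reshape(cube.lines, cube.samples)

    sig = None
    if model.config.probabilistic:
        s = sigma95(model, x)
        sig = np.full(cube.lines * cube.samples, np.nan)
        sig[np.nonzero(sel)[0][in_range]] = s[in_range]
        sig = sig.reshape(cube.lines, cube.samples)

    valid = np.isfinite(spad)
    return PredictionMap(
        spad=spad, sigma95=sig, valid=valid,
        n_masked=int(mask.sum()), n_invalid=n_invalid,
        provenance={
            "model": model.name,
            "strategy": model.strategy,
            "predictor_set": pset,
            "seed": model.seed,
            "campaign": campaign,
            "training_campaigns": list(model.training_campaigns),
        })


def plant_average(pmap: PredictionMap, layout: FieldLayout,
                  plant_ids: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Mean SPAD (and mean sigma95) per plant cell of the sowing matrix.

    ``plant_ids`` assigns each pixel a flat plant index (row-major) or
    -1; when omitted it is derived from the layout's cell geometry.
    Returns ``(means, sigma_means, counts)`` shaped (n_rows, n_cols);
    cells without any valid pixel are NaN with count 0.
    """
    if plant_ids is None:
        plant_ids = _layout_plant_ids(layout, pmap.spad.shape)
    plant_ids = np.asarray(plant_ids)
    if plant_ids.shape != pmap.spad.shape:
        raise HyperspadError("plant_ids geometry does not match the map")
    if np.any((plant_ids < 0) & pmap.valid & (plant_ids != -1)):
        raise HyperspadError("negative plant id other than -1")
    if np.any(pmap.valid & (plant_ids == -1)):
        raise HyperspadError("masked-in pixel not assigned to a plant cell")

    n_cells = layout.n_rows * layout.n_cols
    flat_ids = plant_ids.reshape(-1)
    flat_spad = pmap.spad.reshape(-1)
    ok = np.isfinite(flat_spad) & (flat_ids >= 0)
    counts = np.bincount(flat_ids[ok], minlength=n_cells)
    sums = np.bincount(flat_ids[ok], weights=flat_spad[ok],
                       minlength=n_cells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sigma_means = None
    if pmap.sigma95 is not None:
        flat_sig = pmap.sigma95.reshape(-1)
        oks = np.isfinite(flat_sig) & (flat_ids >= 0)
        csum = np.bincount(flat_ids[oks], weights=flat_sig[oks],
                           minlength=n_cells)
        ccnt = np.bincount(flat_ids[oks], minlength=n_cells)
        sigma_means = np.where(ccnt > 0, csum / np.maximum(ccnt, 1),
                               np.nan).reshape(layout.n_rows, layout.n_cols)
    return (means.reshape(layout.n_rows, layout.n_cols), sigma_means,
            counts.reshape(layout.n_rows, layout.n_cols))


def _layout_plant_ids(layout: FieldLayout, shape: tuple) -> np.ndarray:
    """Plant-cell assignment from the synthetic cube's block geometry."""
    lines, samples = shape
    ids = np.full(shape, -1, dtype=int)
    cell, pad, side = layout.cell, layout.soil_pad, layout.px_per_plant
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            l0, s0 = r * cell + pad, c * cell + pad
            if l0 + side <= lines and s0 + side <= samples:
                ids[l0:l0 + side, s0:s0 + side] = r * layout.n_cols + c
    return ids
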