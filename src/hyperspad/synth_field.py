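"""Synthetic multi-temporal field data with the structure the pipeline assumes.

The generator emulates a five-campaign leaf-phenotyping study of a wild
tomato crop: per-campaign SPAD distributions matching published box-plot
summaries, leaf reflectance spectra whose chlorophyll absorption features
respond monotonically to SPAD, and small georectified data-cubes with a
plant grid, soil background, calibration panels and a plant-delineation
mask.  Everything is seeded and bit-reproducible.

SPAD law
--------
Samples are drawn by inverse-CDF from the piecewise-linear quantile
function through the five-number summary (min, Q1, median, Q3, max).
This reproduces the published box plots exactly (a parametric bounded
family such as a scaled Beta cannot match the whisker endpoints at
finite sample size because its density vanishes at the support edges).

Spectrum model
--------------
A Beer–Lambert-style attenuation of a smooth leaf baseline::

    R(lambda) = [A_vis (1 - L(lambda)) + P L(lambda)] * exp(-k(lambda) c(SPAD))

where ``L`` is a logistic red-edge transition, ``P`` the per-sample NIR
plateau, ``k`` a sum of Gaussian pigment absorbers (Chl-a ~430/680 nm,
Chl-b ~460/650 nm plus a broad green term), and ``c(SPAD)`` an
exponential chlorophyll link reflecting the mostly exponential
SPAD-to-chlorophyll relation reported for many species.  An optional
per-campaign multiplicative drift of the link makes the SPAD-to-spectrum
mapping non-stationary across campaigns — the situation cumulative
retraining is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import HyperspadError
from .spectral_io import ReflectanceCube, SampleTable, SensorModel
import pandas as pd

__all__ = [
    "CampaignSpec",
    "LeafSpectrumModel",
    "FieldLayout",
    "FieldScene",
    "WAVELENGTHS_1NM",
    "default_campaigns",
    "simulate_spad",
    "spad_quantile",
    "simulate_leaf_spectrum",
    "simulate_samples",
    "simulate_cube",
    "soil_spectrum",
    "PANEL_REFLECTANCES",
    "DEFAULT_GAINS",
    "DEFAULT_OFFSETS",
]

WAVELENGTHS_1NM = np.arange(400.0, 1001.0)

#: Nominal reflectance of the six near-Lambertian gray-scale panels.
PANEL_REFLECTANCES = np.array([0.03, 0.06, 0.12, 0.24, 0.40, 0.56])

SPAD_RANGE = (0.0, 70.0)


@dataclass(frozen=True)
class CampaignSpec:
    """One field campaign: SPAD distribution and spectra summary statistics.

    ``spad_dist`` is the five-number summary (min, Q1, median, Q3, max) in
    SPAD units; ``green_peak_mean/sd`` and ``nir_mean/sd`` are reflectance
    fractions describing the campaign's green-peak and NIR-plateau
    statistics; ``drift`` is a scalar perturbation of the chlorophyll link
    (0 = stationary mapping).
    """

    label: str
    spad_dist: tuple[float, float, float, float, float]
    n_samples: int
    green_peak_mean: float
    green_peak_sd: float
    nir_mean: float
    nir_sd: float
    drift: float = 0.0

    def __post_init__(self) -> None:
        d = self.spad_dist
        if len(d) != 5 or not all(a <= b for a, b in zip(d, d[1:])):
            raise HyperspadError(
                f"five-number summary must be ordered, got {d}"
            )
        if d[0] < SPAD_RANGE[0] or d[4] > SPAD_RANGE[1]:
            raise HyperspadError(f"SPAD summary {d} outside {SPAD_RANGE}")
        for v in (self.green_peak_mean, self.green_peak_sd,
                  self.nir_mean, self.nir_sd):
            if not (0.0 <= v <= 1.0):
                raise HyperspadError("reflectance stats must lie in [0, 1]")
        if self.n_samples < 0:
            raise HyperspadError("n_samples must be >= 0")


def default_campaigns(drift: bool = True) -> list[CampaignSpec]:
    """The five default campaigns (establishment through pre-harvest).

    Box medians/quartiles and the n=108 (last campaign 75) sample counts
    follow the study conditions; whisker values not printed there are
    filled with plausible defaults.  ``drift=False`` zeroes the
    per-campaign link perturbation (stationary control).
    """
    rows = [
        # label, (min, q1, med, q3, max), n, green mu/sd, nir mu/sd, drift
        ("20171109", (22, 29, 33, 38, 46), 108, 0.18, 0.02, 0.49, 0.03, 0.00),
        ("20171123", (35, 45, 49, 54, 62), 108, 0.15, 0.03, 0.55, 0.10, 0.08),
        ("20171207", (38, 48, 52, 56, 67), 108, 0.15, 0.03, 0.50, 0.10, -0.07),
        ("20171221", (38, 48, 53, 59, 68), 108, 0.15, 0.03, 0.50, 0.10, 0.12),
        ("20180114", (40, 50, 55, 59, 66), 75, 0.15, 0.03, 0.45, 0.10, -0.10),
    ]
    return [
        CampaignSpec(label=lab, spad_dist=dist, n_samples=n,
                     green_peak_mean=gm, green_peak_sd=gs,
                     nir_mean=nm, nir_sd=ns,
                     drift=dr if drift else 0.0)
        for lab, dist, n, gm, gs, nm, ns, dr in rows
    ]


def simulate_spad(spec: CampaignSpec, seed: int) -> np.ndarray:
    """Draw ``spec.n_samples`` SPAD values matching the five-number summary.

    Inverse-CDF sampling from the piecewise-linear quantile function through
    (0, min), (0.25, Q1), (0.5, median), (0.75, Q3), (1, max).
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=spec.n_samples)
    return spad_quantile(spec, u)


def spad_quantile(spec: CampaignSpec, p) -> np.ndarray:
    """Closed-form quantile function of the campaign's SPAD law."""
    return np.interp(np.asarray(p, dtype=float),
                     [0.0, 0.25, 0.5, 0.75, 1.0], list(spec.spad_dist))


# ---------------------------------------------------------------------------
# Leaf spectra
# ---------------------------------------------------------------------------

def _default_absorbers() -> tuple[tuple[float, float, float], ...]:
    # (center nm, Gaussian sigma nm, strength): Chl-a 430/680, Chl-b 460/650,
    # broad green absorption giving the mild green decline with SPAD.
    return ((430.0, 18.0, 1.20), (460.0, 18.0, 0.90),
            (650.0, 16.0, 0.55), (680.0, 13.0, 0.95),
            (545.0, 40.0, 0.05))


@dataclass(frozen=True)
class LeafSpectrumModel:
    """Parameters of the Beer–Lambert-style leaf reflectance generator."""

    vis_level: float = 0.191           # pigment-free visible reflectance
    red_edge_center: float = 710.0     # logistic transition inflection, nm
    red_edge_width: float = 18.0       # logistic scale, nm
    absorber_bands: tuple = field(default_factory=_default_absorbers)
    chl_tau: float = 25.0              # c(SPAD) = exp(SPAD/tau) - 1
    noise_sd: float = 0.004            # additive per-wavelength noise
    residual_floor: float = 0.03       # surface reflectance no pigment absorbs

    def chl_link(self, spad, drift: float = 0.0) -> np.ndarray:
        """Effective absorber strength; strictly increasing in SPAD."""
        c = np.expm1(np.asarray(spad, dtype=float) / self.chl_tau)
        return c * (1.0 + drift)

    def absorption(self, wavelengths: np.ndarray) -> np.ndarray:
        k = np.zeros_like(wavelengths, dtype=float)
        for center, sigma, strength in self.absorber_bands:
            k += strength * np.exp(-0.5 * ((wavelengths - center) / sigma) ** 2)
        return k

    def logistic(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.red_edge_center) / self.red_edge_width
        return 1.0 / (1.0 + np.exp(-z))


def simulate_leaf_spectrum(
    spad: float,
    model: LeafSpectrumModel,
    campaign: CampaignSpec,
    seed: int,
    noise: bool = True,
    wavelengths: np.ndarray = WAVELENGTHS_1NM,
) -> np.ndarray:
    """One 1-nm leaf reflectance spectrum (400–1,000 nm) for a SPAD value."""
    if not (SPAD_RANGE[0] <= spad <= SPAD_RANGE[1]):
        raise HyperspadError(f"SPAD {spad} outside {SPAD_RANGE}")
    rng = np.random.default_rng(seed)
    plateau = campaign.nir_mean
    vis = model.vis_level
    if noise:
        plateau = float(np.clip(rng.normal(campaign.nir_mean, campaign.nir_sd),
                                0.15, 0.85))
        rel = campaign.green_peak_sd / max(campaign.green_peak_mean, 1e-9)
        vis = vis * float(np.clip(rng.normal(1.0, rel), 0.5, 1.5))
    L = model.logistic(wavelengths)
    baseline = vis * (1.0 - L) + plateau * L
    c = model.chl_link(spad, campaign.drift)
    floor = model.residual_floor
    refl = floor + (baseline - floor) * np.exp(
        -model.absorption(wavelengths) * c)
    if noise:
        refl = refl + rng.normal(0.0, model.noise_sd, size=refl.shape)
    return np.clip(refl, 1e-3, 1.0)


#: SPAD reading error: ~1 unit meter accuracy plus environmental biases
#: of a few units; the same budget that motivates the 5-unit selection
#: threshold.
SPAD_NOISE_SD = 1.5


def simulate_samples(
    campaigns: list[CampaignSpec],
    model: LeafSpectrumModel | None = None,
    seed: int = 0,
    noise: bool = True,
    spad_noise_sd: float = SPAD_NOISE_SD,
) -> SampleTable:
    """Sample table across campaigns: keys, SPAD, and 1-nm spectra columns.

    Three leaflets per plant, mirroring the field sampling protocol.
    The latent SPAD drives the spectrum; the recorded ``spad`` column
    carries meter observation error (``spad_noise_sd``, clipped to the
    meter range), like a real ground-truth campaign.
    """
    model = model or LeafSpectrumModel()
    root = np.random.default_rng(seed)
    frames = []
    for spec in campaigns:
        latent = simulate_spad(spec, int(root.integers(2**31)))
        spad = latent
        if noise and spad_noise_sd > 0:
            spad = np.clip(latent + root.normal(0.0, spad_noise_sd,
                                                size=latent.shape),
                           *SPAD_RANGE)
        spectra = np.empty((spec.n_samples, WAVELENGTHS_1NM.size))
        for i, s in enumerate(latent):
            spectra[i] = simulate_leaf_spectrum(
                s, model, spec, int(root.integers(2**31)), noise=noise)
        df = pd.DataFrame(spectra,
                          columns=[f"{w:.0f}" for w in WAVELENGTHS_1NM])
        df.insert(0, "campaign", spec.label)
        df.insert(1, "plant_id", [i // 3 + 1 for i in range(spec.n_samples)])
        df.insert(2, "leaflet_id", [i % 3 + 1 for i in range(spec.n_samples)])
        df.insert(3, "spad", spad)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return SampleTable(data)


# ---------------------------------------------------------------------------
# Field cubes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldLayout:
    """Sowing arrangement and imaging geometry of the (mini) field."""

    n_rows: int = 12
    n_cols: int = 5
    plant_spacing: float = 1.5
    n_plots: int = 4
    pixel_size: float = 0.007
    px_per_plant: int = 3     # side of the square plant footprint, pixels
    soil_pad: int = 1         # soil pixels around each plant footprint

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise HyperspadError("pixel_size must be positive")
        if (self.n_rows * self.n_cols) % self.n_plots != 0:
            raise HyperspadError(
                f"{self.n_rows}x{self.n_cols} plants not divisible into "
                f"{self.n_plots} plots"
            )

    @property
    def plants_per_plot(self) -> int:
        return self.n_rows * self.n_cols // self.n_plots

    @property
    def cell(self) -> int:
        """Pixel side of one plant cell (footprint + surrounding soil)."""
        return self.px_per_plant + 2 * self.soil_pad

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(lines, samples) of the plant-grid region of the cube."""
        return self.n_rows * self.cell, self.n_cols * self.cell


#: Full-field default: 60 rows x 20 columns in 4 plots (300 plants each).
FULL_FIELD = FieldLayout(n_rows=60, n_cols=20, n_plots=4)

DEFAULT_GAINS = None   # filled per sensor in simulate_cube
DEFAULT_OFFSETS = None


def soil_spectrum(sensor: SensorModel) -> np.ndarray:
    """Smooth bright soil spectrum on the sensor grid (sandy loam-like)."""
    w = sensor.band_centers
    return 0.12 + 0.25 * (w - 400.0) / 600.0


@dataclass
class FieldScene:
    """A simulated scene: cube plus everything needed to validate it."""

    cube: ReflectanceCube
    mask: np.ndarray                 # bool, True = plant pixel
    plant_ids: np.ndarray            # int, flat plant index or -1
    plant_spads: np.ndarray          # (n_rows, n_cols) ground truth
    panel_radiance: np.ndarray       # (bands, 6)
    panel_reflectance: np.ndarray    # (bands, 6)
    gains: np.ndarray | None         # per-band gain (radiance mode)
    offsets: np.ndarray | None
    layout: FieldLayout


def simulate_cube(
    layout: FieldLayout,
    plant_spads: np.ndarray,
    model: LeafSpectrumModel,
    spec: CampaignSpec,
    seed: int,
    sensor: SensorModel | None = None,
    noise: bool = True,
    radiance: bool = False,
    pixel_noise_sd: float = 0.003,
) -> FieldScene:
    """Build a mini data-cube from a matrix of per-plant SPAD values.

    Each plant occupies a ``px_per_plant`` square centered in its cell,
    surrounded by soil; a bottom strip holds the six calibration panels.
    In radiance mode the cube stores per-band affine-distorted values
    (radiance = (reflectance - offset) / gain) so an empirical-line fit
    can recover the gains and offsets exactly on noise-free data.
    """
    from .preprocess import gaussian_resample  # local import, no cycle

    sensor = sensor or SensorModel()
    plant_spads = np.asarray(plant_spads, dtype=float)
    if plant_spads.shape != (layout.n_rows, layout.n_cols):
        raise HyperspadError(
            f"plant_spads shape {plant_spads.shape} does not match layout "
            f"({layout.n_rows}, {layout.n_cols})"
        )
    rng = np.random.default_rng(seed)
    grid_lines, samples = layout.grid_shape
    panel_strip = layout.cell
    lines = grid_lines + panel_strip
    n_bands = sensor.n_bands

    data = np.empty((lines, samples, n_bands), dtype=np.float32)
    data[:] = soil_spectrum(sensor).astype(np.float32)
    mask = np.zeros((lines, samples), dtype=bool)
    plant_ids = np.full((lines, samples), -1, dtype=int)

    cell, pad, side = layout.cell, layout.soil_pad, layout.px_per_plant
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            spec1nm = simulate_leaf_spectrum(
                plant_spads[r, c], model, spec,
                int(rng.integers(2**31)), noise=noise)
            spec272 = gaussian_resample(spec1nm, WAVELENGTHS_1NM, sensor)
            l0, s0 = r * cell + pad, c * cell + pad
            block = np.broadcast_to(
                spec272, (side, side, n_bands)).astype(np.float32).copy()
            if noise:
                bright = rng.normal(1.0, 0.02, size=(side, side, 1))
                block = block * bright + rng.normal(
                    0.0, pixel_noise_sd, size=block.shape)
            data[l0:l0 + side, s0:s0 + side] = np.clip(block, 0.0, 1.0)
            mask[l0:l0 + side, s0:s0 + side] = True
            plant_ids[l0:l0 + side, s0:s0 + side] = r * layout.n_cols + c

    # Six flat gray panels in the bottom strip.
    panel_w = max(1, samples // (2 * PANEL_REFLECTANCES.size))
    panel_reflectance = np.tile(PANEL_REFLECTANCES, (n_bands, 1))
    for j, rho in enumerate(PANEL_REFLECTANCES):
        s0 = j * panel_w
        data[grid_lines:grid_lines + layout.cell, s0:s0 + panel_w] = rho

    gains = offsets = None
    panel_radiance = panel_reflectance.copy()
    if radiance:
        gains = np.linspace(1.5, 3.0, n_bands)
        offsets = np.linspace(0.02, 0.08, n_bands)
        data = ((data - offsets.astype(np.float32))
                / gains.astype(np.float32))
        panel_radiance = (panel_reflectance - offsets[:, None]) / gains[:, None]

    cube = ReflectanceCube(data=data, sensor=sensor,
                           pixel_size=layout.pixel_size)
    return FieldScene(cube=cube, mask=mask, plant_ids=plant_ids,
                      plant_spads=plant_spads,
                      panel_radiance=panel_radiance,
                      panel_reflectance=panel_reflectance,
                      gains=gains, offsets=offsets, layout=layout)
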