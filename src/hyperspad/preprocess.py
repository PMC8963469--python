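"""Spectral conditioning chain: resampling, calibration, smoothing, denoising.

The order mirrors standard hyperspectral practice: 1-nm field spectra are
resampled onto the camera grid with Gaussian spectral-response functions;
at-sensor radiance cubes are converted to surface reflectance with a
per-band empirical-line fit against gray calibration panels; spectra are
smoothed with a Savitzky–Golay filter; cubes are denoised by a minimum
noise fraction (MNF) transform truncated to the high-SNR components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import CoverageError, HyperspadError, RankDeficiencyError
from .spectral_io import ReflectanceCube, SampleTable, SensorModel

__all__ = [
    "gaussian_resample",
    "resample_table",
    "empirical_line_fit",
    "apply_empirical_line",
    "savgol_smooth",
    "mnf_denoise",
    "EmpiricalLineFit",
    "SG_WINDOW",
    "SG_POLYORDER",
]

log = logging.getLogger(__name__)

#: FWHM-to-sigma conversion for a Gaussian spectral response function.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: Savitzky–Golay defaults (bands); configurable in every caller.
SG_WINDOW = 11
SG_POLYORDER = 2


def _resample_matrix(wavelengths: np.ndarray,
                     sensor: SensorModel) -> np.ndarray:
    """(n_bands, n_input) Gaussian SRF weight matrix.

    Each band's window is truncated at +/-3 sigma, shrunk symmetrically
    where the input span ends, and renormalized — so constants and linear
    ramps are reproduced exactly at every band center.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or np.any(np.diff(wavelengths) <= 0):
        raise ValueError("input wavelengths must be strictly increasing 1-D")
    lo, hi = wavelengths[0], wavelengths[-1]
    centers, fwhm = sensor.band_centers, sensor.fwhm
    if lo > centers[0] or hi < centers[-1]:
        raise CoverageError(
            f"input span [{lo}, {hi}] nm does not cover sensor band centers "
            f"[{centers[0]}, {centers[-1]}] nm"
        )
    weights = np.zeros((sensor.n_bands, wavelengths.size))
    for b, (c, f) in enumerate(zip(centers, fwhm)):
        sigma = f / FWHM_TO_SIGMA
        half = min(3.0 * sigma, c - lo, hi - c)
        sel = np.abs(wavelengths - c) <= half + 1e-9
        d = wavelengths[sel] - c
        w = np.exp(-0.5 * (d / sigma) ** 2)
        w = w / w.sum()
        # First-moment correction: the input grid points are not exactly
        # symmetric about a band center, which would bias linear spectra
        # (worst at the edge bands).  Rescale weights by alpha + beta*d so
        # that sum(w) = 1 and sum(w*d) = 0 exactly.
        m = float(w @ d)
        v = float(w @ d**2)
        if v > m * m:
            beta = m / (m * m - v)
            alpha = -beta * v / m if m != 0.0 else 1.0
            w = w * (alpha + beta * d)
        weights[b, sel] = w
    return weights


def gaussian_resample(spectrum: np.ndarray, wavelengths: np.ndarray,
                      sensor: SensorModel) -> np.ndarray:
    """Resample 1-nm spectra onto the sensor grid via Gaussian SRFs.

    ``spectrum`` may be 1-D ``(n_wl,)`` or 2-D ``(n_spectra, n_wl)``;
    sigma = FWHM / 2.3548 per band.  Inputs extending below 400 nm or
    above 1,000 nm (e.g. full-range field-spectrometer output) are
    cropped to the sensor span first.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = sensor.band_centers[0], sensor.band_centers[-1]
    keep = (wavelengths >= lo - 10.0) & (wavelengths <= hi + 10.0)
    if not keep.all():
        wavelengths = wavelengths[keep]
        spectrum = spectrum[..., keep]
    weights = _resample_matrix(wavelengths, sensor)
    return spectrum @ weights.T


def resample_table(table: SampleTable, sensor: SensorModel) -> SampleTable:
    """Resample every spectrum of a 1-nm sample table onto the sensor grid."""
    import pandas as pd

    resampled = gaussian_resample(table.spectra, table.wavelengths, sensor)
    df = table.data[["campaign", "plant_id", "leaflet_id", "spad"]].copy()
    cols = pd.DataFrame(resampled,
                        columns=[f"{w:.4f}" for w in sensor.band_centers],
                        index=df.index)
    return SampleTable(pd.concat([df, cols], axis=1))


# ---------------------------------------------------------------------------
# Empirical line calibration
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalLineFit:
    """Per-band affine map radiance -> reflectance plus fit residuals."""

    gains: np.ndarray
    offsets: np.ndarray
    residuals: np.ndarray   # (bands, panels) reflectance residuals

    @property
    def rmse_per_band(self) -> np.ndarray:
        return np.sqrt(np.mean(self.residuals**2, axis=1))


def empirical_line_fit(panel_radiance: np.ndarray,
                       panel_reflectance: np.ndarray) -> EmpiricalLineFit:
    """Least-squares affine fit per band from >= 2 calibration panels.

    Inputs are ``(bands, n_panels)``; reflectance = gain * radiance + offset.
    """
    rad = np.asarray(panel_radiance, dtype=float)
    refl = np.asarray(panel_reflectance, dtype=float)
    if rad.shape != refl.shape or rad.ndim != 2:
        raise ValueError("panel arrays must both be (bands, n_panels)")
    if rad.shape[1] < 2:
        raise RankDeficiencyError("need >= 2 panels for an affine fit")
    spread = rad.max(axis=1) - rad.min(axis=1)
    bad = np.nonzero(spread <= 0)[0]
    if bad.size:
        raise RankDeficiencyError(
            f"panels are identical in band(s) {bad.tolist()[:5]}; "
            "affine fit is rank-deficient"
        )
    rad_mean = rad.mean(axis=1, keepdims=True)
    refl_mean = refl.mean(axis=1, keepdims=True)
    dr = rad - rad_mean
    gains = np.sum(dr * (refl - refl_mean), axis=1) / np.sum(dr * dr, axis=1)
    offsets = refl_mean[:, 0] - gains * rad_mean[:, 0]
    fitted = gains[:, None] * rad + offsets[:, None]
    return EmpiricalLineFit(gains=gains, offsets=offsets,
                            residuals=refl - fitted)


def apply_empirical_line(cube: ReflectanceCube, gains: np.ndarray,
                         offsets: np.ndarray) -> tuple[ReflectanceCube, int]:
    """Convert a radiance cube to reflectance; clip to [0, 1] and count.

    Returns the corrected cube and the number of clipped values.
    """
    gains = np.asarray(gains, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if gains.shape != (cube.bands,) or offsets.shape != (cube.bands,):
        raise ValueError(
            f"gains/offsets length must equal band count {cube.bands}"
        )
    out = cube.data * gains.astype(np.float32) + offsets.astype(np.float32)
    n_clipped = int(np.count_nonzero((out < 0.0) | (out > 1.0)))
    if n_clipped:
        log.info("empirical line: clipped %d out-of-range values", n_clipped)
    out = np.clip(out, 0.0, 1.0)
    return ReflectanceCube(data=out, sensor=cube.sensor,
                           pixel_size=cube.pixel_size,
                           nodata=cube.nodata), n_clipped


# ---------------------------------------------------------------------------
# Savitzky–Golay smoothing
# ---------------------------------------------------------------------------

def savgol_smooth(spectrum: np.ndarray, window: int = SG_WINDOW,
                  polyorder: int = SG_POLYORDER) -> np.ndarray:
    """Savitzky–Golay smoothing along the last (band) axis.

    Window must be odd and larger than ``polyorder``; edges use local
    polynomial interpolation so polynomial inputs of degree <= polyorder
    are exact fixed points.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window >= spectrum.shape[-1]:
        raise ValueError(
            f"window {window} >= spectrum length {spectrum.shape[-1]}"
        )
    return savgol_filter(spectrum, window, polyorder, axis=-1, mode="interp")


# ---------------------------------------------------------------------------
# Minimum noise fraction
# ---------------------------------------------------------------------------

def _noise_covariance(data: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Noise covariance from horizontal 1-pixel shift differences.

    Differences are taken only between neighboring pixels that are both
    inside the mask, avoiding plant/soil edges.
    """
    left = data[:, :-1, :]
    right = data[:, 1:, :]
    if mask is not None:
        pair = mask[:, :-1] & mask[:, 1:]
    else:
        pair = np.ones(left.shape[:2], dtype=bool)
    if pair.sum() < 2:
        raise HyperspadError("not enough neighboring pixel pairs for MNF")
    diffs = (right[pair] - left[pair]).astype(float)
    return np.cov(diffs, rowvar=False) / 2.0


def mnf_denoise(cube: ReflectanceCube, k: int | None = None,
                mask: np.ndarray | None = None
                ) -> tuple[ReflectanceCube, dict]:
    """MNF transform, truncation to the top-``k`` SNR components, inverse.

    The noise covariance is estimated from horizontal shift differences;
    components are ordered by noise-whitened eigenvalue (estimated SNR).
    With ``k=None`` components with whitened eigenvalue > 1 are kept.  A
    singular noise estimate is regularized (with a warning), which makes
    the duplicate-pixel cube a fixed point.

    Returns the denoised cube and an info dict with ``eigenvalues``,
    ``k`` and ``regularized``.
    """
    if k is not None and k <= 0:
        raise ValueError("k must be positive")
    if k is not None and k > cube.bands:
        raise ValueError(f"k={k} exceeds band count {cube.bands}")
    data = cube.data.astype(float)
    n_pix = data.shape[0] * data.shape[1]
    x = data.reshape(n_pix, cube.bands)

    sigma_n = _noise_covariance(data, mask)
    regularized = False
    eps = 1e-10 * max(np.trace(sigma_n) / cube.bands, 1.0)
    evals_n = np.linalg.eigvalsh(sigma_n)
    if evals_n[0] < eps:
        warnings.warn("singular noise covariance in MNF; regularizing",
                      RuntimeWarning, stacklevel=2)
        sigma_n = sigma_n + eps * np.eye(cube.bands)
        regularized = True

    mu = x.mean(axis=0)
    sigma = np.cov(x - mu, rowvar=False)

    # Whiten the noise, then diagonalize the whitened signal covariance.
    en, vn = np.linalg.eigh(sigma_n)
    whiten = vn / np.sqrt(en)
    c = whiten.T @ sigma @ whiten
    ev, u = np.linalg.eigh(c)
    order = np.argsort(ev)[::-1]
    ev, u = ev[order], u[:, order]
    t = whiten @ u                     # forward transform (columns)
    t_inv = np.linalg.inv(t)

    if k is None:
        k = int(max(1, np.count_nonzero(ev > 1.0)))
    y = (x - mu) @ t[:, :k]
    recon = y @ t_inv[:k, :] + mu
    out = ReflectanceCube(
        data=recon.reshape(data.shape).astype(np.float32),
        sensor=cube.sensor, pixel_size=cube.pixel_size, nodata=cube.nodata)
    return out, {"eigenvalues": ev, "k": k, "regularized": regularized}
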