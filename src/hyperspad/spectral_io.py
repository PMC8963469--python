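"""Readers and writers for the formats the pipeline touches.

Two on-disk formats are supported:

* ENVI-style reflectance cubes — a raw binary file plus a text ``.hdr``
  sidecar with lowercase keys (``samples``, ``lines``, ``bands``,
  ``interleave``, ``data type``, ``wavelength``, ``fwhm``).  BSQ, BIL and
  BIP interleaves are read; the in-memory layout is always
  ``(lines, samples, bands)`` with the band axis last.
* CSV sample tables — one row per (campaign, plant, leaflet) with a SPAD
  reading and one column per wavelength.

Reflectance is stored as 32-bit float fractions in [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CorruptFileError,
    IntegrityError,
    MetadataError,
    SchemaError,
)

__all__ = [
    "SensorModel",
    "ReflectanceCube",
    "SampleTable",
    "read_cube",
    "write_cube",
    "read_samples",
    "write_samples",
]

N_BANDS = 272
KEY_COLUMNS = ["campaign", "plant_id", "leaflet_id"]


def _default_centers() -> np.ndarray:
    return np.linspace(400.0, 1000.0, N_BANDS)


@dataclass(frozen=True)
class SensorModel:
    """Band centers and FWHM of the imaging spectrometer grid.

    The default models a 272-band push-broom camera spanning 400–1,000 nm
    with a constant 6 nm full width at half maximum.
    """

    band_centers: np.ndarray = field(default_factory=_default_centers)
    fwhm: np.ndarray = field(default_factory=lambda: np.full(N_BANDS, 6.0))

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        fwhm = np.broadcast_to(
            np.asarray(self.fwhm, dtype=float), centers.shape
        ).copy()
        object.__setattr__(self, "band_centers", centers)
        object.__setattr__(self, "fwhm", fwhm)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("band_centers must be a 1-D array of >= 2 bands")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(fwhm <= 0):
            raise ValueError("fwhm must be positive")

    @property
    def n_bands(self) -> int:
        return self.band_centers.size

    @property
    def spacing(self) -> float:
        """Mean band-to-band spacing in nm."""
        return float(np.mean(np.diff(self.band_centers)))

    def nearest_band(self, wavelength: float) -> int:
        """Index of the band center closest to ``wavelength`` (nm)."""
        lo, hi = self.band_centers[0], self.band_centers[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside sensor span [{lo}, {hi}]"
            )
        return int(np.argmin(np.abs(self.band_centers - wavelength)))


@dataclass
class ReflectanceCube:
    """A banded raster: ``data[line, sample, band]`` reflectance fractions."""

    data: np.ndarray
    sensor: SensorModel
    pixel_size: float = 0.007
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (lines, samples, bands)")
        if self.data.shape[2] != self.sensor.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands, sensor declares "
                f"{self.sensor.n_bands}"
            )

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# ENVI-style cube I/O
# ---------------------------------------------------------------------------

_DTYPE_CODES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64,
                12: np.uint16}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def _header_path(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix == ".hdr":
        return p
    return p.with_suffix(p.suffix + ".hdr")


def _format_list(values) -> str:
    return "{ " + ", ".join(f"{v:.6f}" for v in values) + " }"


def write_cube(cube: ReflectanceCube, path: str | Path,
               interleave: str = "bsq") -> Path:
    """Write ``cube`` as raw binary + ``.hdr`` sidecar; returns the data path.

    ``interleave`` is one of ``bsq`` (band sequential), ``bil`` (band
    interleaved by line) or ``bip`` (band interleaved by pixel).
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    path = Path(path)
    data = cube.data.astype(np.float32)
    if interleave == "bsq":       # (bands, lines, samples)
        ondisk = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":     # (lines, bands, samples)
        ondisk = np.transpose(data, (0, 2, 1))
    else:                         # bip: (lines, samples, bands)
        ondisk = data
    ondisk = np.ascontiguousarray(ondisk)
    path.parent.mkdir(parents=True, exist_ok=True)
    ondisk.tofile(path)

    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODE_FOR_DTYPE[np.dtype(np.float32)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"pixel size = {{ {cube.pixel_size:.6f}, {cube.pixel_size:.6f} }}",
        f"data ignore value = {cube.nodata}",
        "wavelength = " + _format_list(cube.sensor.band_centers),
        "fwhm = " + _format_list(cube.sensor.fwhm),
    ]
    _header_path(path).write_text("\n".join(lines) + "\n")
    return path


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a dict of lowercase keys -> str or list."""
    # Join brace-delimited lists that may span lines.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            inner = value.strip("{} ")
            items = [v.strip() for v in inner.split(",") if v.strip()]
            fields[key] = items
        else:
            fields[key] = value
    return fields


def read_cube(path: str | Path) -> ReflectanceCube:
    """Read an ENVI-style cube; returns data with the band axis last."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise MetadataError(f"missing header file {hdr}")
    fields = _parse_header(hdr.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", 4))
        interleave = str(fields.get("interleave", "bsq")).lower()
    except (KeyError, ValueError) as exc:
        raise MetadataError(f"header {hdr} lacks a required key: {exc}") from exc
    if "wavelength" not in fields:
        raise MetadataError(f"header {hdr} has no wavelength list")
    wavelength = np.array([float(v) for v in fields["wavelength"]])
    if wavelength.size != bands:
        raise MetadataError(
            f"header declares {bands} bands but lists {wavelength.size} "
            "wavelengths"
        )
    if "fwhm" in fields:
        fwhm = np.array([float(v) for v in fields["fwhm"]])
    else:
        fwhm = np.full(bands, 6.0)
    dtype = np.dtype(_DTYPE_CODES.get(dtype_code))

    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise CorruptFileError(
            f"{path}: header implies {expected} values "
            f"({lines}x{samples}x{bands}), file holds {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise MetadataError(f"unknown interleave {interleave!r} in {hdr}")

    pixel_size = 0.007
    if "pixel size" in fields:
        pixel_size = float(fields["pixel size"][0])
    nodata = float(fields.get("data ignore value", "nan"))
    sensor = SensorModel(band_centers=wavelength, fwhm=fwhm)
    return ReflectanceCube(data=np.ascontiguousarray(data), sensor=sensor,
                           pixel_size=pixel_size, nodata=nodata)


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-leaflet samples: keys, SPAD response, and spectral features.

    ``data`` holds the columns ``campaign, plant_id, leaflet_id, spad``
    followed by one float column per wavelength (column name = nm value).
    Campaign order is the order of first appearance, preserved across I/O.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS + ["spad"] if c not in self.data]
        if missing:
            raise SchemaError(f"sample table missing columns {missing}")
        try:
            [float(c) for c in self.wavelength_columns]
        except ValueError as exc:
            raise SchemaError(f"non-numeric wavelength column: {exc}") from exc
        dup = self.data.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = self.data.loc[dup, KEY_COLUMNS].iloc[0].tolist()
            raise IntegrityError(f"duplicate sample key {keys}")

    @property
    def wavelength_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in KEY_COLUMNS + ["spad"]]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([float(c) for c in self.wavelength_columns])

    @property
    def spectra(self) -> np.ndarray:
        """(n_samples, n_wavelengths) matrix of reflectance fractions."""
        return self.data[self.wavelength_columns].to_numpy(dtype=float)

    @property
    def spad(self) -> np.ndarray:
        return self.data["spad"].to_numpy(dtype=float)

    @property
    def campaign(self) -> np.ndarray:
        return self.data["campaign"].to_numpy()

    @property
    def campaigns(self) -> list:
        """Campaign labels in order of first appearance."""
        return list(pd.unique(self.data["campaign"]))

    def n_per_campaign(self) -> dict:
        return {c: int((self.campaign == c).sum()) for c in self.campaigns}

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))


def write_samples(table: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
    return path


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, dtype={"campaign": str})
    return SampleTable(df)
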