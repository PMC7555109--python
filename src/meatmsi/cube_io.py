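"""Multispectral cube I/O, reflectance calibration, mean spectra.

A cube is stored on disk as a multi-page TIFF (one 32-bit float page per
band, pages in ascending wavelength order) together with a JSON sidecar
carrying the band wavelengths (nm) and the pixel size (um/px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class MultispectralCube:
    """Height x width x bands reflectance image with band metadata."""

    pixels: np.ndarray
    wavelengths: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a 3-D (H, W, bands) array")
        if self.pixels.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"cube has {self.pixels.shape[2]} bands but "
                f"{len(self.wavelengths)} wavelengths"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("cube contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class CalibrationSet:
    """White and dark reference cubes used for reflectance correction."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark cubes must share a shape")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: MultispectralCube, path) -> None:
    """Write a cube as multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.pixels.astype(np.float32), -1, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths],
        "pixel_size_um": float(cube.pixel_size),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_cube(path) -> MultispectralCube:
    """Read a cube written by :func:`write_cube`.

    Raises ``FileNotFoundError`` naming the sidecar when the JSON metadata
    is missing, and ``ValueError`` when the TIFF page count disagrees with
    the sidecar's wavelength list.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar metadata {sidecar} "
            "(expected wavelengths_nm and pixel_size_um)"
        )
    meta = json.loads(sidecar.read_text())
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(wavelengths):
        raise ValueError(
            f"{path} has {pages.shape[0]} pages but sidecar lists "
            f"{len(wavelengths)} wavelengths"
        )
    return MultispectralCube(pixels=np.ascontiguousarray(
                                 np.moveaxis(pages, 0, -1)),
                             wavelengths=wavelengths,
                             pixel_size=float(meta["pixel_size_um"]))


def reflectance_correct(raw: np.ndarray | MultispectralCube,
                        cal: CalibrationSet,
                        wavelengths: np.ndarray | None = None,
                        pixel_size: float | None = None
                        ) -> MultispectralCube:
    """Reflectance R = (raw - dark) / (white - dark), clipped to [0, 1]."""
    if isinstance(raw, MultispectralCube):
        data = np.asarray(raw.pixels, dtype=float)
        wavelengths = raw.wavelengths if wavelengths is None else wavelengths
        pixel_size = raw.pixel_size if pixel_size is None else pixel_size
    else:
        data = np.asarray(raw, dtype=float)
        if wavelengths is None:
            wavelengths = np.arange(data.shape[-1], dtype=float)
        if pixel_size is None:
            pixel_size = 1.0
    if cal.white.shape != data.shape:
        raise ValueError("calibration cubes must match the raw cube shape")
    denom = cal.white - cal.dark
    if np.any(denom <= 0):
        raise ValueError(
            "white reference does not exceed dark reference at every "
            "pixel/band (division by zero in reflectance correction)"
        )
    corrected = np.clip((data - cal.dark) / denom, 0.0, 1.0)
    return MultispectralCube(pixels=corrected, wavelengths=wavelengths,
                             pixel_size=float(pixel_size))


def mean_spectrum(cube: MultispectralCube,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Area-normalized mean spectrum (per-band spatial mean, sum = 1)."""
    pixels = cube.pixels
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pixels.shape[:2]:
            raise ValueError("mask shape must match the image plane")
        if not mask.any():
            raise ValueError("mask is empty")
        spectrum = pixels[mask].mean(axis=0, dtype=np.float64)
    else:
        spectrum = pixels.mean(axis=(0, 1), dtype=np.float64)
    total = spectrum.sum()
    if total == 0:
        raise ValueError("cannot area-normalize an all-zero spectrum")
    return np.asarray(spectrum / total, dtype=float)


def write_spectrum_csv(wavelengths: np.ndarray, spectrum: np.ndarray,
                       path) -> None:
    """Two-column CSV (wavelength_nm, normalized_reflectance)."""
    pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, dtype=float),
                  "normalized_reflectance": np.asarray(spectrum, dtype=float)}
                 ).to_csv(path, index=False)
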