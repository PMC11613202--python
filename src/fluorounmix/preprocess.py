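"""Raw-cube preprocessing: dark subtraction, sensitivity correction, binning.

Turns a raw acquisition triplet (fluorescence cube, white-light cube, dark
cube) into the binned, corrected :class:`~fluorounmix.spectral_core.SpectrumPair`
list the unmixing methods consume.  Steps, in order:

1. subtract the dark cube (sensor dark noise), clamping at zero,
2. divide each band by filter transmission x camera sensitivity,
3. average non-overlapping b x b pixel blocks (default 10 x 10),
4. mask the sample (threshold + morphological opening + largest component),
5. emit one unlabeled SpectrumPair per retained binned pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .spectral_core import HyperCube, SpectrumPair, WavelengthGrid


@dataclass
class SensitivityCurves:
    """Per-band filter transmission and camera quantum sensitivity."""

    filter_transmission: np.ndarray
    camera_sensitivity: np.ndarray

    def __post_init__(self) -> None:
        self.filter_transmission = np.asarray(self.filter_transmission, dtype=float)
        self.camera_sensitivity = np.asarray(self.camera_sensitivity, dtype=float)
        if self.filter_transmission.shape != self.camera_sensitivity.shape:
            raise ValueError("curves must share one length")
        if np.any(self.filter_transmission <= 0) or np.any(self.camera_sensitivity <= 0):
            raise ValueError("sensitivity curves must be strictly positive")

    @classmethod
    def unit(cls, grid: WavelengthGrid) -> "SensitivityCurves":
        ones = np.ones(grid.n_bands)
        return cls(ones, ones.copy())

    def to_csv(self, path: str | Path, grid: WavelengthGrid) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": grid.wavelengths,
                "filter_transmission": self.filter_transmission,
                "camera_sensitivity": self.camera_sensitivity,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensitivityCurves":
        df = pd.read_csv(path)
        return cls(
            df["filter_transmission"].to_numpy(float),
            df["camera_sensitivity"].to_numpy(float),
        )


def subtract_dark(cube: HyperCube, dark: HyperCube) -> HyperCube:
    """Remove sensor dark noise; negatives clamp to zero."""
    if cube.shape != dark.shape or cube.grid != dark.grid:
        raise ValueError("cube and dark cube must share shape and grid")
    out = np.clip(cube.data - dark.data, 0.0, None)
    return HyperCube(out, cube.grid, role=cube.role, exposure_ms=cube.exposure_ms)


def correct_sensitivity(cube: HyperCube, curves: SensitivityCurves) -> HyperCube:
    """Divide band i by filter_transmission[i] * camera_sensitivity[i]."""
    gain = curves.filter_transmission * curves.camera_sensitivity
    if gain.shape != (cube.grid.n_bands,):
        raise ValueError("curve length must equal the cube band count")
    out = cube.data / gain[:, None, None]
    return HyperCube(out, cube.grid, role=cube.role, exposure_ms=cube.exposure_ms)


def bin_pixels(cube: HyperCube, b: int = 10) -> HyperCube:
    """Average non-overlapping b x b pixel blocks; remainder rows/cols drop."""
    if b <= 0:
        raise ValueError("bin size must be a positive integer")
    m, h, w = cube.shape
    hb, wb = h // b, w // b
    if hb < 1 or wb < 1:
        raise ValueError(f"cube {h}x{w} too small for {b}x{b} binning")
    d = cube.data[:, : hb * b, : wb * b]
    out = d.reshape(m, hb, b, wb, b).mean(axis=(2, 4))
    return HyperCube(out, cube.grid, role=cube.role, exposure_ms=cube.exposure_ms)


def mask_foreground(white_cube: HyperCube, opening_radius: int = 1) -> np.ndarray:
    """Sample mask from a binned white cube: Otsu threshold on band-integrated
    intensity, morphological opening (disk radius 1 binned pixel), largest
    connected component."""
    intensity = white_cube.data.sum(axis=0)
    if np.ptp(intensity) == 0:
        raise ValueError("uniform white image: no foreground can be detected")
    thr = threshold_otsu(intensity)
    mask = intensity > thr
    # Chebyshev-radius-1 footprint (3x3 square): removes speckles while
    # preserving rectangular sample boundaries exactly
    size = 2 * opening_radius + 1
    mask = morphology.opening(mask, np.ones((size, size), bool))
    if not mask.any():
        raise ValueError(
            "empty foreground after thresholding/opening "
            f"(threshold={thr:.4g}, intensity range "
            f"[{intensity.min():.4g}, {intensity.max():.4g}])"
        )
    labels = measure.label(mask, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    return labels == counts.argmax()


def extract_pairs(
    fluo_cube: HyperCube,
    white_cube: HyperCube,
    dark_cube: HyperCube,
    curves: SensitivityCurves | None = None,
    b: int = 10,
    mask: np.ndarray | None = None,
) -> list[SpectrumPair]:
    """Full preprocessing pipeline on an aligned cube triplet.

    Returns one unlabeled pair per binned pixel retained by the mask
    (computed from the binned white cube when not supplied).
    """
    if fluo_cube.shape != white_cube.shape or fluo_cube.grid != white_cube.grid:
        raise ValueError("fluorescence and white cubes must be aligned")
    if curves is None:
        curves = SensitivityCurves.unit(fluo_cube.grid)
    fluo = correct_sensitivity(subtract_dark(fluo_cube, dark_cube), curves)
    white = correct_sensitivity(subtract_dark(white_cube, dark_cube), curves)
    fluo_b = bin_pixels(fluo, b)
    white_b = bin_pixels(white, b)
    if mask is None:
        mask = mask_foreground(white_b)
    if mask.shape != fluo_b.data.shape[1:]:
        raise ValueError("mask shape must match the binned image")
    rows, cols = np.nonzero(mask)
    grid = fluo_cube.grid
    return [
        SpectrumPair(
            phi_fluo=fluo_b.data[:, r, c],
            phi_ref=white_b.data[:, r, c],
            grid=grid,
            group_id=f"px_{r}_{c}",
        )
        for r, c in zip(rows, cols)
    ]
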