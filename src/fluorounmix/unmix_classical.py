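"""Classical benchmark: linear mixing model, dual-band correction, NNLS.

The linear mixing model treats a measured fluorescence emission spectrum as a
non-negative combination of K known endmember emission spectra,

    phi_fluo = B z,   z >= 0,

so unmixing is non-negative least squares.  Before unmixing, the measured
spectrum is corrected for heterogeneous tissue absorption/scattering and
geometry with the dual-band normalization: integrate the white-light
reflectance over two wavelength bands, raise the first integral to an
empirical exponent, and use the product as a per-pixel scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .spectral_core import (
    AbundanceVector,
    EndmemberLibrary,
    SpectrumPair,
    WavelengthGrid,
)


@dataclass(frozen=True)
class DualBandConfig:
    """Band edges (nm) and empirical exponent of the dual-band correction.

    The original description fixes neither the bands nor the exponent; the
    defaults integrate an excitation-side reflectance band (450-480 nm) and
    the PpIX emission band (620-640 nm), with exponent 0.7.
    """

    band_a: tuple[float, float] = (450.0, 480.0)
    band_b: tuple[float, float] = (620.0, 640.0)
    exponent: float = 0.7

    def __post_init__(self) -> None:
        for lo, hi in (self.band_a, self.band_b):
            if not (lo < hi):
                raise ValueError("band edges must satisfy lo < hi")
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")


def mix(B: EndmemberLibrary, z: AbundanceVector | np.ndarray) -> np.ndarray:
    """Forward model: sum_k z_k * endmember_k = B @ z."""
    zv = z.z if isinstance(z, AbundanceVector) else np.asarray(z, dtype=float)
    if zv.shape != (B.K,):
        raise ValueError(f"abundance length {zv.shape} does not match K={B.K}")
    return B.B @ zv


def nnls_unmix(phi: np.ndarray, B: EndmemberLibrary) -> AbundanceVector:
    """argmin_{z >= 0} ||B z - phi||^2 via active-set NNLS."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (B.grid.n_bands,):
        raise ValueError("spectrum length must match the library grid")
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite values in spectrum")
    z, _ = _scipy_nnls(B.B, phi)
    return AbundanceVector(z)


def _band_integral(
    phi: np.ndarray, grid: WavelengthGrid, band: tuple[float, float]
) -> float:
    idx = grid.band_indices(*band)
    if idx.size < 2:
        raise ValueError(f"band {band} covers fewer than 2 grid points")
    w = grid.wavelengths[idx]
    return float(np.trapezoid(phi[idx], w))


def dual_band_factor(
    phi_ref: np.ndarray, grid: WavelengthGrid, cfg: DualBandConfig = DualBandConfig()
) -> float:
    """Scale factor s = (int_a phi_ref)^x * (int_b phi_ref), trapezoid rule."""
    phi_ref = np.asarray(phi_ref, dtype=float)
    ia = _band_integral(phi_ref, grid, cfg.band_a)
    ib = _band_integral(phi_ref, grid, cfg.band_b)
    if ia <= 0 or ib <= 0:
        raise ValueError(
            f"non-positive band integral (a={ia:.4g}, b={ib:.4g}): "
            "saturated or empty reflectance"
        )
    return float(ia**cfg.exponent * ib)


def correct_dual_band(
    pair: SpectrumPair, cfg: DualBandConfig = DualBandConfig()
) -> np.ndarray:
    """Attenuation-corrected fluorescence spectrum: phi_fluo / s."""
    s = dual_band_factor(pair.phi_ref, pair.grid, cfg)
    return pair.phi_fluo / s


def classical_pipeline(
    pair: SpectrumPair,
    B: EndmemberLibrary,
    cfg: DualBandConfig = DualBandConfig(),
) -> AbundanceVector:
    """Dual-band correction followed by NNLS unmixing."""
    return nnls_unmix(correct_dual_band(pair, cfg), B)
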