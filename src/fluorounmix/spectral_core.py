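"""Domain types and I/O for hyperspectral fluorescence spectra.

The measurement model: a liquid-crystal tunable filter sweeps the visible
range (by default 421-730 nm in 3 nm steps, 104 bands) while a camera captures
one grayscale image per band, yielding a data cube.  Each binned pixel carries
two spectra: the fluorescence emission under 405 nm excitation (``phi_fluo``)
and the white-light reflectance (``phi_ref``) used for attenuation correction.

This module houses the wavelength grid, the spectrum-pair container, the
endmember library (matrix ``B`` of pure fluorophore emission spectra), the
abundance vector, the hyperspectral cube, and plain-text readers/writers for
each (CSV for spectra tables and endmember libraries, ENVI ``.hdr``/``.raw``
band-sequential for cubes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

UNIT_TAGS = ("ug_per_ml", "pmol_per_mg", "unlabeled")

DEFAULT_ENDMEMBER_NAMES = ("ppix634", "ppix620", "lipofuscin", "nadh", "flavins")


class SpectraFormatError(ValueError):
    """A file does not conform to the expected spectra-table / ENVI layout."""


class SpectraValidationError(ValueError):
    """Well-formed file, invalid content (e.g. negative intensities)."""


# ---------------------------------------------------------------------------
# Wavelength grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling: wavelength(i) = start_nm + i * step_nm."""

    start_nm: float = 421.0
    step_nm: float = 3.0
    n_bands: int = 104

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("a wavelength grid needs at least 2 bands")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive (strictly increasing grid)")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    @property
    def stop_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_bands - 1)

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands with lo_nm <= wavelength <= hi_nm."""
        w = self.wavelengths
        return np.nonzero((w >= lo_nm) & (w <= hi_nm))[0]

    @classmethod
    def from_wavelengths(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        w = np.asarray(wavelengths, dtype=float)
        if w.size < 2:
            raise ValueError("need at least 2 wavelengths")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6):
            raise ValueError("wavelengths are not uniformly spaced")
        return cls(start_nm=float(w[0]), step_nm=float(steps[0]), n_bands=int(w.size))


# ---------------------------------------------------------------------------
# Spectrum pair
# ---------------------------------------------------------------------------


@dataclass
class SpectrumPair:
    """One binned pixel: fluorescence + white-light spectra, optional label.

    ``c_ppix`` is the known PpIX concentration (ug/mL for phantoms, pmol/mg
    for brain homogenate) and must be present exactly when ``unit_tag`` is not
    ``"unlabeled"``.
    """

    phi_fluo: np.ndarray
    phi_ref: np.ndarray
    grid: WavelengthGrid
    c_ppix: float | None = None
    group_id: str = ""
    unit_tag: str = "unlabeled"

    def __post_init__(self) -> None:
        self.phi_fluo = np.asarray(self.phi_fluo, dtype=float)
        self.phi_ref = np.asarray(self.phi_ref, dtype=float)
        m = self.grid.n_bands
        if self.phi_fluo.shape != (m,) or self.phi_ref.shape != (m,):
            raise ValueError(
                f"spectra must have length {m}, got {self.phi_fluo.shape} / {self.phi_ref.shape}"
            )
        if np.any(self.phi_fluo < 0) or np.any(self.phi_ref < 0):
            raise SpectraValidationError("negative intensities in spectrum pair")
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(f"unit_tag must be one of {UNIT_TAGS}")
        if self.unit_tag == "unlabeled":
            if self.c_ppix is not None:
                raise ValueError("unlabeled pair must not carry a concentration")
        else:
            if self.c_ppix is None:
                raise ValueError(f"unit_tag={self.unit_tag!r} requires c_ppix")
            if self.c_ppix < 0:
                raise ValueError("c_ppix must be non-negative")

    @property
    def labeled(self) -> bool:
        return self.unit_tag != "unlabeled"


# ---------------------------------------------------------------------------
# Endmember library
# ---------------------------------------------------------------------------


@dataclass
class EndmemberLibrary:
    """Matrix B (m x K) of pure fluorophore emission spectra, peak-normalized.

    Columns are normalized so each endmember's maximum is 1; abundances then
    carry all magnitude.  ``scale_factors`` records the factor each column was
    divided by on construction/loading, so raw libraries can be recovered.
    """

    B: np.ndarray
    names: tuple[str, ...]
    grid: WavelengthGrid
    scale_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.names = tuple(self.names)
        m, k = self.B.shape
        if m != self.grid.n_bands:
            raise ValueError("B row count must equal the grid band count")
        if k < 1 or len(self.names) != k:
            raise ValueError("need one name per endmember column, K >= 1")
        if np.any(self.B < 0):
            raise ValueError("endmember spectra must be non-negative")
        peaks = self.B.max(axis=0)
        if np.any(peaks <= 0):
            raise ValueError("every endmember must have positive peak intensity")
        self.B = self.B / peaks
        if self.scale_factors is None:
            self.scale_factors = peaks
        if np.linalg.matrix_rank(self.B) < k:
            raise ValueError("endmember columns are linearly dependent")

    @property
    def K(self) -> int:
        return self.B.shape[1]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.B, columns=list(self.names))
        df.insert(0, "wavelength_nm", self.grid.wavelengths)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EndmemberLibrary":
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise SpectraFormatError("endmember CSV needs a 'wavelength_nm' column")
        grid = WavelengthGrid.from_wavelengths(df["wavelength_nm"].to_numpy())
        names = [c for c in df.columns if c != "wavelength_nm"]
        return cls(df[names].to_numpy(float), tuple(names), grid)


# ---------------------------------------------------------------------------
# Abundance vector
# ---------------------------------------------------------------------------


@dataclass
class AbundanceVector:
    """Non-negative endmember abundances z and the unit-l2 relative form."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("z must be a vector")
        if np.any(self.z < -1e-12):
            raise ValueError("abundances must be non-negative")
        self.z = np.clip(self.z, 0.0, None)

    @property
    def z_hat(self) -> np.ndarray:
        n = np.linalg.norm(self.z)
        if n == 0:
            return np.zeros_like(self.z)
        return self.z / n


def normalize_l2(x: np.ndarray) -> np.ndarray:
    """x / ||x||2, with the all-zero vector mapped to itself."""
    n = np.linalg.norm(x)
    return x if n == 0 else x / n


# ---------------------------------------------------------------------------
# Hyperspectral cube
# ---------------------------------------------------------------------------

CUBE_ROLES = ("fluorescence", "white", "dark")


@dataclass
class HyperCube:
    """Band-major image stack (m x H x W) with wavelength grid and role."""

    data: np.ndarray
    grid: WavelengthGrid
    role: str = "fluorescence"
    exposure_ms: float = 500.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (bands, rows, cols)")
        if self.data.shape[0] != self.grid.n_bands:
            raise ValueError("band count must equal grid.n_bands")
        if self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise ValueError("cube must have at least one pixel")
        if self.role not in CUBE_ROLES:
            raise ValueError(f"role must be one of {CUBE_ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Spectra tables (CSV)
# ---------------------------------------------------------------------------


def _wavelength_columns(prefix: str, grid: WavelengthGrid) -> list[str]:
    return [f"{prefix}_{w:.6g}" for w in grid.wavelengths]


def _parse_wavelength_columns(columns: Sequence[str], prefix: str) -> list[tuple[str, float]]:
    pat = re.compile(rf"^{prefix}_([0-9]+(?:\.[0-9]+)?)$")
    out = []
    for c in columns:
        mobj = pat.match(c)
        if mobj:
            out.append((c, float(mobj.group(1))))
    return out


def write_spectra_table(pairs: Sequence[SpectrumPair], path: str | Path) -> None:
    """Write pairs to CSV (self-describing: wavelengths live in column names)."""
    path = Path(path)
    if len(pairs) == 0:
        grid = WavelengthGrid()
        cols = ["group_id", "unit_tag", "c_ppix"] + _wavelength_columns("f", grid) + _wavelength_columns("w", grid)
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    grid = pairs[0].grid
    for p in pairs:
        if p.grid != grid:
            raise ValueError("all pairs must share one wavelength grid")
    fcols = _wavelength_columns("f", grid)
    wcols = _wavelength_columns("w", grid)
    rows = {
        "group_id": [p.group_id for p in pairs],
        "unit_tag": [p.unit_tag for p in pairs],
        "c_ppix": [p.c_ppix if p.c_ppix is not None else np.nan for p in pairs],
    }
    fl = np.stack([p.phi_fluo for p in pairs])
    wh = np.stack([p.phi_ref for p in pairs])
    df = pd.DataFrame(rows)
    df = pd.concat(
        [df, pd.DataFrame(fl, columns=fcols), pd.DataFrame(wh, columns=wcols)], axis=1
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path: str | Path) -> list[SpectrumPair]:
    """Read a spectra table written by :func:`write_spectra_table`."""
    df = pd.read_csv(path)
    fparsed = _parse_wavelength_columns(df.columns, "f")
    wparsed = _parse_wavelength_columns(df.columns, "w")
    if not fparsed or not wparsed:
        raise SpectraFormatError("spectra table needs f_<nm> and w_<nm> columns")
    if len(fparsed) != len(wparsed):
        raise SpectraFormatError(
            f"mismatched band counts: {len(fparsed)} fluorescence vs {len(wparsed)} white columns"
        )
    fw = [w for _, w in fparsed]
    ww = [w for _, w in wparsed]
    if not np.allclose(fw, ww):
        raise SpectraFormatError("fluorescence and white wavelength grids differ")
    grid = WavelengthGrid.from_wavelengths(fw)
    fcols = [c for c, _ in fparsed]
    wcols = [c for c, _ in wparsed]
    fl = df[fcols].to_numpy(float)
    wh = df[wcols].to_numpy(float)
    pairs: list[SpectrumPair] = []
    for i in range(len(df)):
        if np.any(fl[i] < 0) or np.any(wh[i] < 0):
            raise SpectraValidationError(f"negative intensity in row {i}")
        c = df["c_ppix"].iloc[i] if "c_ppix" in df.columns else np.nan
        tag = str(df["unit_tag"].iloc[i]) if "unit_tag" in df.columns else "unlabeled"
        if pd.isna(c) or tag == "unlabeled" or tag == "nan":
            tag, cval = "unlabeled", None
        else:
            cval = float(c)
        pairs.append(
            SpectrumPair(
                phi_fluo=fl[i],
                phi_ref=wh[i],
                grid=grid,
                c_ppix=cval,
                group_id=str(df["group_id"].iloc[i]) if "group_id" in df.columns else "",
                unit_tag=tag,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# ENVI cubes (.hdr + .raw, BSQ interleave, float32)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}


def write_envi_cube(cube: HyperCube, header_path: str | Path) -> None:
    header_path = Path(header_path)
    raw_path = header_path.with_suffix(".raw")
    m, h, w = cube.shape
    wl = ", ".join(f"{x:.6g}" for x in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{fluorounmix {cube.role} cube}}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {m}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"exposure ms = {cube.exposure_ms:.6g}\n"
        f"cube role = {cube.role}\n"
        f"wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(hdr)
    cube.data.astype("<f4").tofile(raw_path)


def _parse_envi_header(text: str) -> dict[str, str]:
    # Collapse {...} blocks onto one logical line, then split key = value.
    fields: dict[str, str] = {}
    buf = ""
    for line in text.splitlines():
        buf += line.strip() + " "
        if buf.count("{") == buf.count("}"):
            if "=" in buf:
                key, val = buf.split("=", 1)
                fields[key.strip().lower()] = val.strip().strip("{}").strip()
            buf = ""
    return fields


def read_envi_cube(header_path: str | Path) -> HyperCube:
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
    except KeyError as e:
        raise SpectraFormatError(f"ENVI header missing field {e}") from e
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise SpectraFormatError("only BSQ interleave is supported")
    if "wavelength" not in fields:
        raise SpectraFormatError("ENVI header missing wavelength list")
    wavelengths = [float(x) for x in fields["wavelength"].split(",") if x.strip()]
    if len(wavelengths) != bands:
        raise SpectraFormatError(
            f"header lists {len(wavelengths)} wavelengths but {bands} bands"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise SpectraFormatError(f"unsupported ENVI data type {dtype_code}")
    raw_path = header_path.with_suffix(".raw")
    data = np.fromfile(raw_path, dtype=_ENVI_DTYPES[dtype_code])
    if data.size != bands * lines * samples:
        raise SpectraFormatError("raw file size does not match header dimensions")
    grid = WavelengthGrid.from_wavelengths(wavelengths)
    return HyperCube(
        data=data.reshape(bands, lines, samples).astype(float),
        grid=grid,
        role=fields.get("cube role", "fluorescence"),
        exposure_ms=float(fields.get("exposure ms", "500")),
    )


# ---------------------------------------------------------------------------
# Grid resampling
# ---------------------------------------------------------------------------


def resample_to_grid(
    spectrum: np.ndarray, source: WavelengthGrid, target: WavelengthGrid
) -> np.ndarray:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Used to reconcile endmember libraries measured on a different grid with
    the acquisition grid.  Extrapolation is refused.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (source.n_bands,):
        raise ValueError("spectrum length must match the source grid")
    if target.start_nm < source.start_nm - 1e-9 or target.stop_nm > source.stop_nm + 1e-9:
        raise ValueError("target grid extends beyond the source range (extrapolation)")
    return np.interp(target.wavelengths, source.wavelengths, spectrum)
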