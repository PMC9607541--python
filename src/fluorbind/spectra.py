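"""Domain types and delimited-text I/O for emission spectra and titration tables.

Concentrations are stored internally in mol/L; file units are declared in the
manifest (micromolar by default, matching typical albumin-titration practice).
Intensities are instrument-arbitrary fluorescence units.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "SynchronousSeries",
    "PeakEstimate",
    "UNIT_FACTORS",
    "read_manifest",
    "read_titration_table",
    "write_titration_table",
    "read_spectra_table",
    "write_spectra_table",
    "extract_peak_intensity",
    "intensity_at",
]

#: Multiplicative factors converting a declared concentration unit to mol/L.
UNIT_FACTORS: dict[str, float] = {
    "M": 1.0,
    "mol/L": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,  # μM
    "nM": 1e-9,
}


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("expected a 1-D array of values")
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan: intensity versus emission wavelength.

    Parameters
    ----------
    wavelengths : array-like
        Emission wavelengths in nm, strictly increasing.
    intensities : array-like
        Fluorescence intensities (arbitrary units), same length, finite and
        non-negative.
    excitation_wavelength : float, optional
        Excitation wavelength in nm (280 nm excites both Trp and Tyr in
        serum albumin).
    temperature : float
        Sample temperature in kelvin.
    label : str
        Free-text identifier (e.g. the titrant concentration).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float | None = None
    temperature: float = 298.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths)
        inten = _as_float_array(self.intensities)
        if wl.size != inten.size:
            raise ValidationError(
                f"wavelengths ({wl.size}) and intensities ({inten.size}) differ in length"
            )
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValidationError("intensities must be finite")
        if np.any(inten < 0):
            raise ValidationError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class TitrationSeries:
    """Peak fluorescence intensity versus quencher concentration at one temperature.

    ``quencher_conc`` is in mol/L, non-negative, strictly increasing and must
    start at 0; the intensity paired with concentration 0 is the unquenched
    reference F0.
    """

    quencher_conc: np.ndarray
    peak_intensity: np.ndarray
    temperature: float = 298.0
    protein_conc: float | None = None
    readout_wavelength: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        conc = _as_float_array(self.quencher_conc)
        inten = _as_float_array(self.peak_intensity)
        if conc.size != inten.size:
            raise ValidationError(
                f"concentrations ({conc.size}) and intensities ({inten.size}) differ in length"
            )
        if conc.size < 2:
            raise ValidationError("a titration needs at least 2 points")
        if conc[0] != 0.0:
            raise ValidationError("first concentration must be 0 (defines F0)")
        if np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")
        if not np.all(np.diff(conc) > 0):
            raise ValidationError("concentrations must be strictly increasing")
        if np.any(inten <= 0) or not np.all(np.isfinite(inten)):
            raise ValidationError("all intensities must be finite and > 0")
        object.__setattr__(self, "quencher_conc", conc)
        object.__setattr__(self, "peak_intensity", inten)

    @property
    def F0(self) -> float:
        """Unquenched fluorescence intensity (reading at zero quencher)."""
        return float(self.peak_intensity[0])

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.quencher_conc))


@dataclass(frozen=True)
class SynchronousSeries:
    """A stack of synchronous-scan spectra, one per quencher concentration.

    ``delta_lambda`` is the fixed excitation-emission offset: 15 nm isolates
    tyrosine, 60 nm tryptophan.
    """

    delta_lambda: float
    spectra: tuple[EmissionSpectrum, ...]
    quencher_conc: np.ndarray
    allowed_offsets: tuple[float, ...] = (15.0, 60.0)

    def __post_init__(self) -> None:
        conc = _as_float_array(self.quencher_conc)
        spectra = tuple(self.spectra)
        if len(spectra) != conc.size:
            raise ValidationError(
                f"got {len(spectra)} spectra for {conc.size} concentrations"
            )
        if self.allowed_offsets and self.delta_lambda not in self.allowed_offsets:
            raise ValidationError(
                f"delta_lambda {self.delta_lambda} not in allowed offsets {self.allowed_offsets}"
            )
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "quencher_conc", conc)


@dataclass(frozen=True)
class PeakEstimate:
    """Result of band-maximum extraction from a spectrum."""

    wavelength: float
    intensity: float
    reliable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# manifests and tables
# ---------------------------------------------------------------------------

def read_manifest(path) -> dict:
    """Load a key-value manifest (YAML syntax covers plain ``key: value`` text)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"manifest {path} did not parse to a mapping")
    return data


def _unit_factor(units: str) -> float:
    try:
        return UNIT_FACTORS[units]
    except KeyError:
        raise ValidationError(
            f"unknown concentration unit {units!r}; known: {sorted(UNIT_FACTORS)}"
        ) from None


def _read_delimited(path) -> pd.DataFrame:
    # comma/tab auto-detection; decimal point only
    return pd.read_csv(path, sep=None, engine="python")


def read_titration_table(path, manifest: Mapping) -> TitrationSeries:
    """Read a two-column (conc, intensity) delimited-text titration table.

    The manifest declares ``units`` (default μM), ``temperature_K`` and
    optionally ``protein_conc_M`` and ``readout_nm``.  Concentrations are
    converted to mol/L and the series is sorted ascending; a zero-concentration
    row is required and becomes F0.
    """
    df = _read_delimited(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        conc_col = cols["conc"]
        int_col = cols["intensity"]
    except KeyError:
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: need columns 'conc' and 'intensity'") from None
        conc_col, int_col = df.columns[:2]
    conc = df[conc_col].to_numpy(dtype=float)
    inten = df[int_col].to_numpy(dtype=float)

    factor = _unit_factor(str(manifest.get("units", "uM")))
    conc = conc * factor

    dupes = pd.Series(conc).duplicated(keep=False)
    if dupes.any():
        rows = [int(i) for i in np.flatnonzero(dupes.to_numpy())]
        raise ValidationError(f"{path}: duplicate concentrations at rows {rows}")

    order = np.argsort(conc)
    conc, inten = conc[order], inten[order]
    if conc[0] != 0.0:
        raise ValidationError(f"{path}: missing zero-concentration row (required for F0)")
    if np.count_nonzero(conc) < 3:
        raise ValidationError(f"{path}: need ≥3 nonzero concentrations for fitting")

    return TitrationSeries(
        quencher_conc=conc,
        peak_intensity=inten,
        temperature=float(manifest.get("temperature_K", 298.0)),
        protein_conc=manifest.get("protein_conc_M"),
        readout_wavelength=manifest.get("readout_nm"),
        label=str(manifest.get("label", Path(path).stem)),
    )


def write_titration_table(series: TitrationSeries, path, units: str = "M") -> None:
    """Write a titration series as a ``conc,intensity`` CSV in the given unit."""
    factor = _unit_factor(units)
    df = pd.DataFrame(
        {"conc": series.quencher_conc / factor, "intensity": series.peak_intensity}
    )
    df.to_csv(path, index=False, float_format="%.17g")


_INT_COL_RE = re.compile(r"^I_([0-9.eE+\-]+)\s*([A-Za-z/μ]+)$")


def write_spectra_table(
    spectra: Sequence[EmissionSpectrum], concs: Sequence[float], path, units: str = "uM"
) -> None:
    """Write spectra as ``wavelength_nm, I_<conc><unit>, ...`` delimited text."""
    factor = _unit_factor(units)
    if len(spectra) != len(concs):
        raise ValidationError("one concentration per spectrum required")
    wl = spectra[0].wavelengths
    data = {"wavelength_nm": wl}
    for spec, c in zip(spectra, concs):
        if not np.array_equal(spec.wavelengths, wl):
            raise ValidationError("all spectra must share one wavelength grid")
        data[f"I_{c / factor:g}{units}"] = spec.intensities
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path, manifest: Mapping) -> tuple[list[EmissionSpectrum], np.ndarray]:
    """Read a multi-column spectra file; concentrations parsed from headers.

    Returns the spectra (sorted by concentration ascending) and the matching
    concentration array in mol/L.
    """
    df = _read_delimited(path)
    wl_col = df.columns[0]
    wl = df[wl_col].to_numpy(dtype=float)
    temperature = float(manifest.get("temperature_K", 298.0))
    excitation = manifest.get("excitation_nm")
    entries: list[tuple[float, EmissionSpectrum]] = []
    for col in df.columns[1:]:
        m = _INT_COL_RE.match(col.strip())
        if not m:
            raise ValidationError(
                f"{path}: cannot parse concentration from column {col!r} "
                "(expected I_<conc><unit>)"
            )
        conc = float(m.group(1)) * _unit_factor(m.group(2))
        spec = EmissionSpectrum(
            wavelengths=wl,
            intensities=df[col].to_numpy(dtype=float),
            excitation_wavelength=excitation,
            temperature=temperature,
            label=col,
        )
        entries.append((conc, spec))
    entries.sort(key=lambda pair: pair[0])
    concs = np.array([c for c, _ in entries])
    return [s for _, s in entries], concs


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def intensity_at(spectrum: EmissionSpectrum, wavelength: float) -> float:
    """Linearly interpolated intensity at a fixed readout wavelength."""
    wl = spectrum.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValidationError(
            f"readout {wavelength} nm outside spectral range [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(wavelength, wl, spectrum.intensities))


def extract_peak_intensity(
    spectrum: EmissionSpectrum, nominal_peak: float = 340.0, window: float = 20.0
) -> PeakEstimate:
    """Locate the band maximum near ``nominal_peak`` by quadratic-vertex fitting.

    The local maximum nearest the nominal position is found on the sampled
    grid, a quadratic is fitted to all points within ``window`` nm of it, and
    the parabola vertex gives sub-gridpoint wavelength and intensity.  If the
    local maximum sits on the spectral boundary the boundary value is returned
    flagged unreliable.
    """
    wl = spectrum.wavelengths
    inten = spectrum.intensities
    if not (wl[0] <= nominal_peak <= wl[-1]):
        raise ValidationError(
            f"nominal peak {nominal_peak} nm outside spectral range [{wl[0]}, {wl[-1]}]"
        )

    interior = (inten[1:-1] >= inten[:-2]) & (inten[1:-1] >= inten[2:])
    local_max = np.flatnonzero(interior) + 1
    if local_max.size == 0:
        # monotone spectrum: maximum is on a boundary
        idx = int(np.argmax(inten))
        warnings.warn("band maximum on spectral boundary; estimate unreliable")
        return PeakEstimate(float(wl[idx]), float(inten[idx]), reliable=False,
                            note="maximum on spectral boundary")
    idx = int(local_max[np.argmin(np.abs(wl[local_max] - nominal_peak))])

    sel = np.abs(wl - wl[idx]) <= window
    if np.count_nonzero(sel) < 5:
        raise ValidationError(
            f"need ≥5 samples within ±{window} nm of the peak, got {np.count_nonzero(sel)}"
        )
    if idx in (0, wl.size - 1):
        warnings.warn("local maximum on window boundary; returning boundary value")
        return PeakEstimate(float(wl[idx]), float(inten[idx]), reliable=False,
                            note="maximum on window boundary")

    x = wl[sel] - wl[idx]  # centre for conditioning
    a, b, c = np.polyfit(x, inten[sel], 2)
    if a >= 0:
        warnings.warn("no downward curvature at peak; returning grid maximum")
        return PeakEstimate(float(wl[idx]), float(inten[idx]), reliable=False,
                            note="non-concave fit")
    vx = -b / (2.0 * a)
    if abs(vx) > window:
        warnings.warn("quadratic vertex outside fit window; returning grid maximum")
        return PeakEstimate(float(wl[idx]), float(inten[idx]), reliable=False,
                            note="vertex outside window")
    peak_wl = float(wl[idx] + vx)
    peak_int = float(a * vx * vx + b * vx + c)
    return PeakEstimate(peak_wl, peak_int, reliable=True)
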