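"""Impedance and conductivity spectra: domain types, CSV I/O, and the
impedance → admittance conversions.

A tetrapolar sweep yields, per frequency, the real part R and imaginary
part X of the complex impedance Z = R + iX.  The conductance used for the
conductivity conversion is the real part of the admittance Y = 1/Z,

    G(f) = R / (R^2 + X^2)        [siemens]

Reactance is stored as the signed imaginary part of Z, so a capacitive
tissue has X < 0.  The conversion is sign-agnostic (X enters squared); the
sign convention only matters for phase plots.

Frequencies are stored in hertz everywhere inside the library; kilohertz
appears only at the CLI/report layer.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SingularImpedanceError, SpectrumParseError

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "ConductivitySpectrum",
    "MeasurementRecord",
    "TISSUE_CLASSES",
    "STATES",
    "TUMOR_TYPES",
    "conductance_spectrum",
    "to_magnitude_phase",
    "from_magnitude_phase",
    "read_impedance_csv",
    "write_impedance_csv",
    "write_conductivity_csv",
    "read_conductivity_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]

TISSUE_CLASSES = frozenset({"normal", "tumor", "cirrhotic"})
STATES = frozenset({"in_vivo", "ex_vivo"})
TUMOR_TYPES = frozenset({"HCC", "MET", "CCA", "none"})

#: Sweep span of the instrument emulated here: 256 log-spaced points,
#: 3 kHz to 1 MHz inclusive.
DEFAULT_GRID_POINTS = 256
DEFAULT_GRID_SPAN_HZ = (3_000.0, 1_000_000.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, positive measurement frequencies in Hz."""

    hz: np.ndarray

    def __post_init__(self) -> None:
        hz = np.asarray(self.hz, dtype=float)
        object.__setattr__(self, "hz", hz)
        if hz.ndim != 1 or hz.size == 0:
            raise ConfigurationError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(hz)) or np.any(hz <= 0):
            raise ConfigurationError("frequencies must be finite and > 0")
        if np.any(np.diff(hz) <= 0):
            raise ConfigurationError("frequencies must be strictly increasing")

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """256-point logarithmic sweep, endpoints exactly 3 kHz and 1 MHz."""
        lo, hi = DEFAULT_GRID_SPAN_HZ
        return cls(np.geomspace(lo, hi, DEFAULT_GRID_POINTS))

    def __len__(self) -> int:
        return int(self.hz.size)

    def matches(self, other: "FrequencyGrid", rtol: float = 1e-9) -> bool:
        """True when the two grids agree point-by-point within ``rtol``."""
        return len(self) == len(other) and bool(
            np.allclose(self.hz, other.hz, rtol=rtol, atol=0.0)
        )


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Per-frequency complex impedance Z = R + iX of a passive system."""

    grid: FrequencyGrid
    resistance: np.ndarray  # R, ohm, >= 0
    reactance: np.ndarray  # X, ohm, any sign

    def __post_init__(self) -> None:
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)
        n = len(self.grid)
        if r.shape != (n,) or x.shape != (n,):
            raise ConfigurationError(
                f"resistance/reactance must have length {n} to match the grid"
            )
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(x))):
            raise ConfigurationError("R and X must be finite")
        if np.any(r < 0):
            raise ConfigurationError("negative resistance: not a passive system")
        if not np.any(r**2 + x**2 > 0):
            raise ConfigurationError("all-zero impedance spectrum")

    @property
    def z(self) -> np.ndarray:
        """Complex impedance array."""
        return self.resistance + 1j * self.reactance

    @classmethod
    def from_complex(cls, grid: FrequencyGrid, z: np.ndarray) -> "ImpedanceSpectrum":
        z = np.asarray(z, dtype=complex)
        return cls(grid=grid, resistance=z.real.copy(), reactance=z.imag.copy())


@dataclass(frozen=True)
class ConductivitySpectrum:
    """Per-frequency tissue conductivity sigma(f) in S/m."""

    grid: FrequencyGrid
    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", s)
        if s.shape != (len(self.grid),):
            raise ConfigurationError("sigma must have the same length as the grid")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ConfigurationError("conductivity must be finite and > 0")


@dataclass
class MeasurementRecord:
    """One spectrum plus the patient/tissue metadata it was acquired under.

    ``tissue_class`` distinguishes normal parenchyma, tumor, and the
    cirrhotic parenchyma of cirrhotic patients (reported as its own class).
    """

    patient_id: str
    tissue_class: str
    state: str
    spectrum: ImpedanceSpectrum | ConductivitySpectrum
    tumor_type: str = "none"
    tumor_dims_mm: tuple[float, ...] | None = None
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ConfigurationError(f"unknown tissue_class {self.tissue_class!r}")
        if self.state not in STATES:
            raise ConfigurationError(f"unknown state {self.state!r}")
        if self.tumor_type not in TUMOR_TYPES:
            raise ConfigurationError(f"unknown tumor_type {self.tumor_type!r}")
        if (self.tumor_type != "none") != (self.tissue_class == "tumor"):
            raise ConfigurationError(
                "tumor_type must be set exactly when tissue_class is 'tumor' "
                f"(got tissue_class={self.tissue_class!r}, tumor_type={self.tumor_type!r})"
            )
        if self.tumor_dims_mm is not None:
            if self.tissue_class != "tumor":
                raise ConfigurationError("tumor_dims_mm only allowed for tumor records")
            dims = tuple(float(d) for d in self.tumor_dims_mm)
            if not 1 <= len(dims) <= 3 or any(d <= 0 for d in dims):
                raise ConfigurationError("tumor_dims_mm must be 1-3 positive lengths")
            self.tumor_dims_mm = dims

    @property
    def key(self) -> str:
        return f"{self.patient_id}/{self.tissue_class}/{self.state}"

    def with_spectrum(
        self, spectrum: ImpedanceSpectrum | ConductivitySpectrum
    ) -> "MeasurementRecord":
        return dataclasses.replace(self, spectrum=spectrum)


# ---------------------------------------------------------------------------
# conversions


def conductance_spectrum(z: ImpedanceSpectrum) -> np.ndarray:
    """Real part of the admittance, G(f) = R / (R^2 + X^2), in siemens.

    Raises
    ------
    SingularImpedanceError
        If R = X = 0 at any frequency (the admittance is undefined there).
    """
    denom = z.resistance**2 + z.reactance**2
    bad = np.flatnonzero(denom == 0.0)
    if bad.size:
        f = z.grid.hz[bad[0]]
        raise SingularImpedanceError(f"R = X = 0 at {f:g} Hz: admittance undefined")
    return z.resistance / denom


def to_magnitude_phase(z: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency (|Z| in ohm, phase in degrees, in (-180, 180])."""
    mag = np.hypot(z.resistance, z.reactance)
    phase = np.degrees(np.arctan2(z.reactance, z.resistance))
    return mag, phase


def from_magnitude_phase(
    grid: FrequencyGrid, magnitude: np.ndarray, phase_deg: np.ndarray
) -> ImpedanceSpectrum:
    """Inverse of :func:`to_magnitude_phase`."""
    rad = np.radians(np.asarray(phase_deg, dtype=float))
    mag = np.asarray(magnitude, dtype=float)
    return ImpedanceSpectrum(
        grid=grid, resistance=mag * np.cos(rad), reactance=mag * np.sin(rad)
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated, mandatory header row, '.' decimal separator,
# UTF-8.  Floats are written with "%.17g" so read-back is lossless.

IMPEDANCE_COLUMNS = ("frequency_hz", "resistance_ohm", "reactance_ohm")
CONDUCTIVITY_COLUMNS = ("frequency_hz", "conductivity_s_per_m")
FLOAT_FORMAT = "%.17g"


def _read_numeric_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SpectrumParseError(f"no such file: {path}")
    try:
        # round_trip: the default fast parser can be one ulp off
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise SpectrumParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpectrumParseError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: header line plus 1-based counting
            raise SpectrumParseError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at line {bad[0] + 2}"
            )
        df[col] = coerced.astype(float)
    return df


def _sorted_unique_frequencies(df: pd.DataFrame, path: Path | str) -> pd.DataFrame:
    df = df.sort_values("frequency_hz", kind="stable").reset_index(drop=True)
    dup = df["frequency_hz"].duplicated()
    if dup.any():
        f = df.loc[dup.idxmax(), "frequency_hz"]
        raise SpectrumParseError(f"{path}: duplicate frequency {f:g} Hz")
    return df


def read_impedance_csv(path: str | Path) -> ImpedanceSpectrum:
    """Read an impedance sweep; rows are sorted by frequency on the way in."""
    df = _read_numeric_frame(path, IMPEDANCE_COLUMNS)
    df = _sorted_unique_frequencies(df, path)
    try:
        grid = FrequencyGrid(df["frequency_hz"].to_numpy())
        return ImpedanceSpectrum(
            grid=grid,
            resistance=df["resistance_ohm"].to_numpy(),
            reactance=df["reactance_ohm"].to_numpy(),
        )
    except ConfigurationError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def write_impedance_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.grid.hz,
            "resistance_ohm": spectrum.resistance,
            "reactance_ohm": spectrum.reactance,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_conductivity_csv(spectrum: ConductivitySpectrum, path: str | Path) -> None:
    """Write sigma(f); read-back reproduces the input exactly (float64)."""
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.grid.hz,
            "conductivity_s_per_m": spectrum.sigma,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_conductivity_csv(path: str | Path) -> ConductivitySpectrum:
    df = _read_numeric_frame(path, CONDUCTIVITY_COLUMNS)
    df = _sorted_unique_frequencies(df, path)
    try:
        grid = FrequencyGrid(df["frequency_hz"].to_numpy())
        return ConductivitySpectrum(
            grid=grid, sigma=df["conductivity_s_per_m"].to_numpy()
        )
    except ConfigurationError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


# --- cohort metadata -------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id",
    "tissue_class",
    "state",
    "tumor_type",
    "tumor_dims_mm",
    "temperature_c",
    "spectrum_path",
)

_DIMS_SEP = re.compile(r"[x×;]")


def _format_dims(dims: tuple[float, ...] | None) -> str:
    if dims is None:
        return ""
    return "x".join(f"{d:g}" for d in dims)


def _parse_dims(text: str) -> tuple[float, ...] | None:
    text = text.strip()
    if not text:
        return None
    try:
        return tuple(float(t) for t in _DIMS_SEP.split(text) if t.strip())
    except ValueError as exc:
        raise SpectrumParseError(f"unparseable tumor_dims_mm {text!r}") from exc


def write_cohort_csv(
    records: Sequence[MeasurementRecord],
    path: str | Path,
    spectra_dir: str | Path = "spectra",
) -> None:
    """Write cohort metadata plus one spectrum CSV per record.

    Spectrum files are named ``<patient>_<class>_<state>.csv`` inside
    ``spectra_dir`` (resolved relative to the metadata file) and referenced
    from the ``spectrum_path`` column.
    """
    path = Path(path)
    spectra = path.parent / spectra_dir
    spectra.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.patient_id}_{rec.tissue_class}_{rec.state}.csv"
        target = spectra / fname
        if isinstance(rec.spectrum, ImpedanceSpectrum):
            write_impedance_csv(rec.spectrum, target)
        else:
            write_conductivity_csv(rec.spectrum, target)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "tissue_class": rec.tissue_class,
                "state": rec.state,
                "tumor_type": rec.tumor_type,
                "tumor_dims_mm": _format_dims(rec.tumor_dims_mm),
                "temperature_c": "" if rec.temperature_c is None else rec.temperature_c,
                "spectrum_path": f"{Path(spectra_dir) / fname}",
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[MeasurementRecord]:
    """Read cohort metadata; spectrum paths resolve relative to the CSV."""
    path = Path(path)
    if not path.exists():
        raise SpectrumParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumParseError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        spath = path.parent / row["spectrum_path"]
        # auto-detect spectrum flavour from the header
        header = pd.read_csv(spath, nrows=0).columns if spath.exists() else []
        if "conductivity_s_per_m" in header:
            spectrum: ImpedanceSpectrum | ConductivitySpectrum = read_conductivity_csv(
                spath
            )
        else:
            spectrum = read_impedance_csv(spath)
        temp = row["temperature_c"].strip()
        try:
            records.append(
                MeasurementRecord(
                    patient_id=row["patient_id"],
                    tissue_class=row["tissue_class"],
                    state=row["state"],
                    tumor_type=row["tumor_type"] or "none",
                    tumor_dims_mm=_parse_dims(row["tumor_dims_mm"]),
                    temperature_c=float(temp) if temp else None,
                    spectrum=spectrum,
                )
            )
        except ConfigurationError as exc:
            raise SpectrumParseError(f"{path}: line {i + 2}: {exc}") from exc
    return records
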