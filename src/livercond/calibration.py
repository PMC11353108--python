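"""Buffer-based calibration of tetrapolar impedance sweeps.

A saline reference buffer of known conductivity sigma_ref is measured with
the same probe as the tissue.  Because a resistive buffer has a flat
spectrum, any frequency structure in its measured conductance G_buffer(f)
is instrument artifact (stray capacitance, lead inductance).  The
per-frequency conversion factor

    k(f) = sigma_ref / G_buffer(f)          [1/m]

therefore folds both the probe's cell constant and the instrument
distortion into one curve, and tissue conductivity follows as

    sigma_tissue(f) = k(f) * G_tissue(f)    [S/m]

By construction k(f) * G_buffer(f) == sigma_ref exactly at every grid
point, so calibrating the buffer against itself is the identity check.

The default calibration buffer is the 0.25 S/m reference (its impedance is
closest to the tissue low-frequency impedance); the catalogue also holds
0.062 and 0.13 S/m buffers, all specified at 20 degC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateBufferError,
    GridMismatchError,
    LiverCondError,
    SingularImpedanceError,
)
from .spectra import (
    ConductivitySpectrum,
    FrequencyGrid,
    ImpedanceSpectrum,
    MeasurementRecord,
    conductance_spectrum,
)

__all__ = [
    "BUFFER_CATALOGUE",
    "DEFAULT_BUFFER_NAME",
    "ReferenceBuffer",
    "CalibrationCurve",
    "CalibrationConfig",
    "Exclusion",
    "build_calibration",
    "apply_calibration",
    "calibrate_cohort",
    "write_calibration_csv",
]

#: Reference saline conductivities, S/m at 20 degC.
BUFFER_CATALOGUE: dict[str, float] = {
    "Reference #1": 0.062,
    "Reference #2": 0.13,
    "Reference #3": 0.25,
}
DEFAULT_BUFFER_NAME = "Reference #3"
BUFFER_TEMPERATURE_C = 20.0


@dataclass(frozen=True)
class ReferenceBuffer:
    """A measured reference buffer: known sigma_ref plus its impedance sweep."""

    name: str
    sigma_ref: float  # S/m at temperature_c
    spectrum: ImpedanceSpectrum
    temperature_c: float = BUFFER_TEMPERATURE_C

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_ref) and self.sigma_ref > 0):
            raise ConfigurationError("buffer sigma_ref must be finite and > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-frequency conversion factor k(f), 1/m, from one buffer sweep."""

    grid: FrequencyGrid
    k: np.ndarray
    source_buffer: str

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "k", k)
        if k.shape != (len(self.grid),):
            raise ConfigurationError("k must have the same length as the grid")
        if not np.all(np.isfinite(k)) or np.any(k <= 0):
            raise ConfigurationError("k(f) must be finite and > 0")


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunables for cohort calibration.

    ``temp_coeff_pct_per_c`` is an optional linear conductivity-temperature
    correction in %/degC applied about ``temp_ref_c``; it is off by default
    because the measurement protocol applies none (temperature is carried
    as metadata only).
    """

    buffer_name: str = DEFAULT_BUFFER_NAME
    grid_tolerance_rel: float = 1e-9
    temp_coeff_pct_per_c: float | None = None
    temp_ref_c: float = BUFFER_TEMPERATURE_C


def build_calibration(buffer: ReferenceBuffer) -> CalibrationCurve:
    """k(f) = sigma_ref / G_buffer(f), per frequency.

    Raises :class:`DegenerateBufferError` if the buffer conductance is not
    strictly positive everywhere.
    """
    g = conductance_spectrum(buffer.spectrum)
    bad = np.flatnonzero(g <= 0)
    if bad.size:
        f = buffer.spectrum.grid.hz[bad[0]]
        raise DegenerateBufferError(
            f"buffer {buffer.name!r} has G <= 0 at {f:g} Hz"
        )
    return CalibrationCurve(
        grid=buffer.spectrum.grid, k=buffer.sigma_ref / g, source_buffer=buffer.name
    )


def apply_calibration(
    curve: CalibrationCurve,
    tissue: ImpedanceSpectrum,
    grid_tolerance_rel: float = 1e-9,
) -> ConductivitySpectrum:
    """sigma(f) = k(f) * G_tissue(f) on the calibration grid.

    The tissue must be measured on the same sweep as the buffer; a grid
    mismatch raises :class:`GridMismatchError` rather than interpolating
    (interpolation would silently change k(f) where parasitics are steep).
    """
    if not curve.grid.matches(tissue.grid, rtol=grid_tolerance_rel):
        raise GridMismatchError(
            "tissue grid does not match calibration grid "
            f"(n={len(tissue.grid)} vs n={len(curve.grid)}; no interpolation)"
        )
    sigma = curve.k * conductance_spectrum(tissue)
    return ConductivitySpectrum(grid=curve.grid, sigma=sigma)


@dataclass(frozen=True)
class Exclusion:
    """One dropped record with a machine-readable reason code."""

    record_key: str
    reason: str
    detail: str


def _temperature_factor(cfg: CalibrationConfig, record: MeasurementRecord) -> float:
    if cfg.temp_coeff_pct_per_c is None or record.temperature_c is None:
        return 1.0
    return 1.0 + cfg.temp_coeff_pct_per_c / 100.0 * (
        record.temperature_c - cfg.temp_ref_c
    )


def calibrate_cohort(
    records: list[MeasurementRecord],
    buffer: ReferenceBuffer,
    config: CalibrationConfig | None = None,
) -> tuple[list[MeasurementRecord], list[Exclusion]]:
    """Calibrate every record's impedance sweep to a conductivity spectrum.

    Metadata is untouched.  Records whose spectra cannot be converted
    (singular impedance, grid mismatch, non-positive conductivity) are
    dropped and returned as :class:`Exclusion` entries instead of failing
    the whole cohort — mirroring the exclusion of technically invalid
    clinical measurements, where per-condition n varies.
    """
    if not records:
        raise ConfigurationError("empty cohort: nothing to calibrate")
    cfg = config or CalibrationConfig()
    curve = build_calibration(buffer)
    kept: list[MeasurementRecord] = []
    dropped: list[Exclusion] = []
    for rec in records:
        if not isinstance(rec.spectrum, ImpedanceSpectrum):
            dropped.append(
                Exclusion(rec.key, "not_impedance", "record already calibrated")
            )
            continue
        try:
            sigma = apply_calibration(
                curve, rec.spectrum, grid_tolerance_rel=cfg.grid_tolerance_rel
            )
            factor = _temperature_factor(cfg, rec)
            if factor != 1.0:
                sigma = ConductivitySpectrum(grid=sigma.grid, sigma=sigma.sigma * factor)
        except SingularImpedanceError as exc:
            dropped.append(Exclusion(rec.key, "singular_impedance", str(exc)))
            continue
        except GridMismatchError as exc:
            dropped.append(Exclusion(rec.key, "grid_mismatch", str(exc)))
            continue
        except (ConfigurationError, LiverCondError) as exc:
            dropped.append(Exclusion(rec.key, "invalid_spectrum", str(exc)))
            continue
        kept.append(rec.with_spectrum(sigma))
    return kept, dropped


def write_calibration_csv(curve: CalibrationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": curve.grid.hz,
            "k_per_m": curve.k,
            "source_buffer": curve.source_buffer,
        }
    ).to_csv(path, index=False, float_format="%.17g")
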