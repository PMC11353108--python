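"""Forward simulator of tetrapolar liver measurements.

Tissue dispersion follows the Cole model

    Z(f) = R_inf + (R_0 - R_inf) / (1 + (i f / f_c)^alpha),

the standard empirical description of the beta-dispersion band: R_0 and
R_inf are the zero- and infinite-frequency resistances, f_c the
characteristic frequency and alpha in (0, 1] the dispersion broadness.
Saline buffers are purely resistive.  Bulk conductivity relates to ideal
(parasitic-free) conductance through the probe cell constant kappa,

    sigma(f) = kappa * G_ideal(f),      kappa in 1/m,

shared by tissue and buffer because the same physical probe measures both.
The instrument sees the tissue through a minimal two-element parasitic
network — series lead inductance L and stray parallel capacitance C:

    Z_meas(f) = i w L + Z(f) / (1 + i w C Z(f)),  w = 2 pi f,

which reproduces the characteristic high-frequency magnitude rise and
phase roll that buffer calibration is there to remove.

The cohort generator draws, per simulated patient, anchor conductivities
(sigma at 3 kHz, sigma at 1 MHz) from truncated normal distributions with
per-group means/SDs defaulting to the published liver study groups, maps
them to Cole parameters via r0 = kappa / sigma_3kHz, r_inf =
kappa / sigma_1MHz, and pins the curve so the parasitic-free conductivity
passes exactly through both anchors (see
:func:`pinned_tissue_impedance`).  Randomness derives from a single
top-level seed via per-group child streams, so adding a group does not
perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .calibration import BUFFER_CATALOGUE, ReferenceBuffer
from .errors import ConfigurationError
from .spectra import (
    ConductivitySpectrum,
    FrequencyGrid,
    ImpedanceSpectrum,
    MeasurementRecord,
)

__all__ = [
    "ColeParameters",
    "DEFAULT_PARASITICS",
    "ParasiticModel",
    "ProbeGeometry",
    "GroupSpec",
    "SimulationConfig",
    "RecordTruth",
    "SimulatedCohort",
    "cole_impedance",
    "buffer_impedance",
    "apply_parasitics",
    "make_reference_buffer",
    "truncated_normal_positive",
    "pinned_tissue_impedance",
    "generate_cohort",
    "default_group_specs",
]

ANCHOR_LOW_HZ = 3_000.0
ANCHOR_HIGH_HZ = 1_000_000.0

#: In vivo tissue sits at body-cavity temperature; ex vivo pieces are
#: measured at theatre ambient.
STATE_TEMPERATURE_C = {"in_vivo": 36.0, "ex_vivo": 20.0}


@dataclass(frozen=True)
class ColeParameters:
    """Cole dispersion parameters of one simulated tissue."""

    r0: float  # zero-frequency resistance, ohm
    r_inf: float  # infinite-frequency resistance, ohm
    fc: float  # characteristic frequency, Hz
    alpha: float  # dispersion broadness, (0, 1]

    def __post_init__(self) -> None:
        if not (self.r0 > self.r_inf > 0):
            raise ConfigurationError("require r0 > r_inf > 0")
        if not self.fc > 0:
            raise ConfigurationError("require fc > 0")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("require 0 < alpha <= 1")


@dataclass(frozen=True)
class ParasiticModel:
    """Series lead inductance and parallel stray capacitance; (0, 0) is ideal."""

    l_series: float = 0.0  # H
    c_parallel: float = 0.0  # F

    def __post_init__(self) -> None:
        if self.l_series < 0 or self.c_parallel < 0:
            raise ConfigurationError("parasitic values must be >= 0")

    def scaled(self, factor: float) -> "ParasiticModel":
        return ParasiticModel(self.l_series * factor, self.c_parallel * factor)


#: Default instrument parasitics: material (>5 % of |Z|) at 1 MHz,
#: negligible at 3 kHz, for ~100-ohm loads.
DEFAULT_PARASITICS = ParasiticModel(l_series=0.5e-6, c_parallel=0.2e-9)


@dataclass(frozen=True)
class ProbeGeometry:
    """In-line four-needle probe geometry and its cell constant.

    Defaults: 0.35 mm needles (radius 0.175 mm), 1 mm spacing, 3 mm active
    tip, 3 mm array span.  ``cell_constant_per_m`` relates ideal
    conductance to bulk conductivity: sigma = kappa * G.
    """

    needle_radius_mm: float = 0.175
    needle_spacing_mm: float = 1.0
    active_tip_mm: float = 3.0
    array_span_mm: float = 3.0
    cell_constant_per_m: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "needle_radius_mm",
            "needle_spacing_mm",
            "active_tip_mm",
            "array_span_mm",
            "cell_constant_per_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """Target distribution of one cohort group.

    Anchor statistics are the group mean and SD of conductivity (S/m) at
    3 kHz (``mean_low``/``sd_low``) and 1 MHz (``mean_high``/``sd_high``).
    For tumor groups either a fixed ``tumor_type`` or per-type sampling
    weights may be given.
    """

    tissue_class: str
    state: str
    n: int
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    tumor_type: str | None = None
    tumor_type_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("group size n must be >= 1")
        for v in (self.mean_low, self.sd_low, self.mean_high, self.sd_high):
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError("group means and SDs must be > 0")

    @property
    def label(self) -> str:
        t = self.tumor_type or ""
        return f"{self.tissue_class}|{self.state}|{t}"


def default_group_specs() -> list[GroupSpec]:
    """The six study groups with their published anchor statistics.

    Group sizes and mean +/- SD of sigma at 3 kHz and 1 MHz per tissue
    class and state; tumor-type weights follow the per-type in vivo
    (HCC 5 / MET 6 / CCA 2) and ex vivo (HCC 6 / MET 6 / CCA 1) counts.
    """
    return [
        GroupSpec("normal", "in_vivo", 15, 0.13, 0.06, 0.49, 0.10),
        GroupSpec("normal", "ex_vivo", 16, 0.12, 0.07, 0.38, 0.08),
        GroupSpec(
            "tumor", "in_vivo", 16, 0.41, 0.10, 0.78, 0.24,
            tumor_type_weights={"HCC": 5, "MET": 6, "CCA": 2},
        ),
        GroupSpec(
            "tumor", "ex_vivo", 3, 0.27, 0.09, 0.54, 0.14,
            tumor_type_weights={"HCC": 6, "MET": 6, "CCA": 1},
        ),
        GroupSpec("cirrhotic", "in_vivo", 3, 0.09, 0.01, 0.41, 0.01),
        GroupSpec("cirrhotic", "ex_vivo", 3, 0.16, 0.01, 0.40, 0.08),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the cohort generator needs; ground truth for recovery tests."""

    seed: int
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    parasitics: ParasiticModel = DEFAULT_PARASITICS
    group_specs: tuple[GroupSpec, ...] = field(
        default_factory=lambda: tuple(default_group_specs())
    )
    cole_fc_range: tuple[float, float] = (50e3, 500e3)
    cole_alpha_range: tuple[float, float] = (0.7, 0.95)

    def __post_init__(self) -> None:
        lo, hi = self.cole_fc_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid cole_fc_range")
        alo, ahi = self.cole_alpha_range
        if not 0 < alo <= ahi <= 1:
            raise ConfigurationError("invalid cole_alpha_range")
        if not self.group_specs:
            raise ConfigurationError("no group specs configured")


# ---------------------------------------------------------------------------
# forward models


def cole_impedance(p: ColeParameters, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate the Cole model on a frequency grid."""
    s = (1j * grid.hz / p.fc) ** p.alpha
    z = p.r_inf + (p.r0 - p.r_inf) / (1.0 + s)
    return ImpedanceSpectrum.from_complex(grid, z)


def buffer_impedance(
    sigma: float, geometry: ProbeGeometry, grid: FrequencyGrid
) -> ImpedanceSpectrum:
    """Ideal resistive buffer: R(f) = kappa / sigma, X = 0 at all f."""
    if not (np.isfinite(sigma) and sigma > 0):
        raise ConfigurationError("buffer sigma must be > 0")
    r = geometry.cell_constant_per_m / sigma
    n = len(grid)
    return ImpedanceSpectrum(
        grid=grid, resistance=np.full(n, r), reactance=np.zeros(n)
    )


def apply_parasitics(z: ImpedanceSpectrum, par: ParasiticModel) -> ImpedanceSpectrum:
    """Distort a true impedance through the series-L / parallel-C network."""
    if par.l_series == 0.0 and par.c_parallel == 0.0:
        return z
    w = 2.0 * np.pi * z.grid.hz
    zt = z.z
    z_meas = 1j * w * par.l_series + zt / (1.0 + 1j * w * par.c_parallel * zt)
    return ImpedanceSpectrum.from_complex(z.grid, z_meas)


def make_reference_buffer(
    name: str,
    geometry: ProbeGeometry,
    grid: FrequencyGrid,
    parasitics: ParasiticModel = ParasiticModel(),
    sigma_ref: float | None = None,
) -> ReferenceBuffer:
    """Simulate measuring a catalogue buffer (parasitics included)."""
    if sigma_ref is None:
        try:
            sigma_ref = BUFFER_CATALOGUE[name]
        except KeyError as exc:
            raise ConfigurationError(f"unknown buffer {name!r}") from exc
    ideal = buffer_impedance(sigma_ref, geometry, grid)
    return ReferenceBuffer(
        name=name, sigma_ref=sigma_ref, spectrum=apply_parasitics(ideal, parasitics)
    )


# ---------------------------------------------------------------------------
# sampling


def truncated_normal_positive(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd) truncated to (0, inf) by rejection.

    Raises :class:`ConfigurationError` when the positive tail has
    probability < 1e-3 (the truncation would distort the target beyond
    recognition and rejection would stall).
    """
    if not (sd > 0 and np.isfinite(mean)):
        raise ConfigurationError("mean/sd invalid for truncated normal")
    if norm.sf(0.0, loc=mean, scale=sd) < 1e-3:
        raise ConfigurationError(
            f"truncated normal infeasible: P(X>0) < 1e-3 for mean={mean}, sd={sd}"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[draw > 0]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _draw_anchor_pair(
    rng: np.random.Generator, spec: GroupSpec, max_attempts: int = 1000
) -> tuple[float, float]:
    """One (sigma_3kHz, sigma_1MHz) pair with sigma_1MHz > sigma_3kHz."""
    for _ in range(max_attempts):
        low = truncated_normal_positive(rng, spec.mean_low, spec.sd_low, 1)[0]
        high = truncated_normal_positive(rng, spec.mean_high, spec.sd_high, 1)[0]
        if high > low:
            return low, high
    raise ConfigurationError(
        f"could not draw sigma_1MHz > sigma_3kHz for group {spec.label!r} "
        f"after {max_attempts} attempts"
    )


def _cole_conductance_at(p: ColeParameters, f_hz: np.ndarray) -> np.ndarray:
    z = p.r_inf + (p.r0 - p.r_inf) / (1.0 + (1j * np.asarray(f_hz) / p.fc) ** p.alpha)
    return z.real / (z.real**2 + z.imag**2)


def pinned_tissue_impedance(
    sigma_low: float,
    sigma_high: float,
    fc: float,
    alpha: float,
    kappa: float,
    grid: FrequencyGrid,
    f_low: float = ANCHOR_LOW_HZ,
    f_high: float = ANCHOR_HIGH_HZ,
) -> tuple[ColeParameters, ImpedanceSpectrum, np.ndarray]:
    """Parasitic-free tissue impedance whose conductivity passes exactly
    through the drawn anchors at ``f_low`` and ``f_high``.

    The Cole parameters come from the anchor map r0 = kappa / sigma_low,
    r_inf = kappa / sigma_high.  Because r0 and r_inf are the f -> 0 and
    f -> inf *limits*, the raw Cole conductivity misses the anchors by a
    few percent at the finite anchor frequencies.  A smooth real scaling
    Z -> s(f) * Z with log(s) linear in log(f) pins both anchors exactly.
    Since G_cole(f_low) >= 1/r0 and G_cole(f_high) <= 1/r_inf always, the
    endpoint corrections satisfy s(f_low) >= 1 >= s(f_high): the ramp only
    ever tilts the conductivity spectrum further upward, so sigma(f) stays
    non-decreasing and every sigma_high > sigma_low pair is representable.

    Returns (ColeParameters, impedance spectrum, sigma_true per grid point).
    """
    if not sigma_high > sigma_low > 0:
        raise ConfigurationError("require sigma_high > sigma_low > 0")
    cole = ColeParameters(
        r0=kappa / sigma_low, r_inf=kappa / sigma_high, fc=fc, alpha=alpha
    )
    s1 = _cole_conductance_at(cole, np.array([f_low]))[0] * kappa / sigma_low
    s2 = _cole_conductance_at(cole, np.array([f_high]))[0] * kappa / sigma_high
    t = (np.log(grid.hz) - np.log(f_low)) / (np.log(f_high) - np.log(f_low))
    s = np.exp(np.log(s1) + t * (np.log(s2) - np.log(s1)))
    z = cole_impedance(cole, grid).z * s
    spectrum = ImpedanceSpectrum.from_complex(grid, z)
    g = spectrum.resistance / (spectrum.resistance**2 + spectrum.reactance**2)
    return cole, spectrum, kappa * g


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class RecordTruth:
    """Ground truth behind one simulated record."""

    cole: ColeParameters
    sigma_true: ConductivitySpectrum  # parasitic-free kappa * Re(1/Z_cole)
    sigma_low: float  # drawn anchor at 3 kHz, S/m
    sigma_high: float  # drawn anchor at 1 MHz, S/m


@dataclass(frozen=True)
class SimulatedCohort:
    """Generator output: measured records, measured buffers, and truth."""

    records: list[MeasurementRecord]
    buffers: dict[str, ReferenceBuffer]
    truth: dict[str, RecordTruth]  # keyed by MeasurementRecord.key
    config: SimulationConfig


def _group_rng(seed: int, label: str, occurrence: int) -> np.random.Generator:
    # crc32 gives a stable, platform-independent child key per group
    key = zlib.crc32(f"{label}#{occurrence}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _draw_tumor_dims(rng: np.random.Generator) -> tuple[float, float, float]:
    """Plausible tumor dimensions: max axis log-uniform 10-90 mm."""
    a = float(np.exp(rng.uniform(np.log(10.0), np.log(90.0))))
    b = a * rng.uniform(0.5, 1.0)
    c = a * rng.uniform(0.5, 1.0)
    dims = sorted((a, b, c), reverse=True)
    return tuple(round(d, 1) for d in dims)  # type: ignore[return-value]


def generate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate the whole study: per-group tissue sweeps plus the three
    reference buffers, everything distorted by the configured parasitics.

    Fully reproducible from ``cfg.seed``; per-record truth (Cole parameters,
    parasitic-free conductivity spectrum, drawn anchors) is returned keyed
    by record.
    """
    kappa = cfg.geometry.cell_constant_per_m
    records: list[MeasurementRecord] = []
    truth: dict[str, RecordTruth] = {}
    seen: dict[str, int] = {}
    for gi, spec in enumerate(cfg.group_specs):
        occurrence = seen.get(spec.label, 0)
        seen[spec.label] = occurrence + 1
        rng = _group_rng(cfg.seed, spec.label, occurrence)
        # gi in the id keeps patient ids (and truth keys) unique even when
        # two groups share tissue_class and state
        short = spec.tissue_class[:3] + {"in_vivo": "iv", "ex_vivo": "ev"}[spec.state]
        for i in range(spec.n):
            low, high = _draw_anchor_pair(rng, spec)
            fc = rng.uniform(*cfg.cole_fc_range)
            alpha = rng.uniform(*cfg.cole_alpha_range)
            cole, ideal, sigma = pinned_tissue_impedance(
                low, high, fc, alpha, kappa, cfg.grid
            )
            measured = apply_parasitics(ideal, cfg.parasitics)
            sigma_true = ConductivitySpectrum(grid=cfg.grid, sigma=sigma)
            if spec.tissue_class == "tumor":
                if spec.tumor_type is not None:
                    ttype = spec.tumor_type
                else:
                    weights = spec.tumor_type_weights or {"HCC": 1, "MET": 1, "CCA": 1}
                    names = sorted(weights)
                    p = np.array([weights[n] for n in names], dtype=float)
                    ttype = str(rng.choice(names, p=p / p.sum()))
                dims = _draw_tumor_dims(rng)
            else:
                ttype, dims = "none", None
            rec = MeasurementRecord(
                patient_id=f"G{gi + 1:02d}-{short}{i + 1:03d}",
                tissue_class=spec.tissue_class,
                state=spec.state,
                tumor_type=ttype,
                tumor_dims_mm=dims,
                temperature_c=STATE_TEMPERATURE_C[spec.state],
                spectrum=measured,
            )
            records.append(rec)
            truth[rec.key] = RecordTruth(
                cole=cole, sigma_true=sigma_true, sigma_low=low, sigma_high=high
            )
    buffers = {
        name: make_reference_buffer(name, cfg.geometry, cfg.grid, cfg.parasitics)
        for name in BUFFER_CATALOGUE
    }
    return SimulatedCohort(records=records, buffers=buffers, truth=truth, config=cfg)
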