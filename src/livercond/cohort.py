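"""Cohort-level conductivity statistics.

Given calibrated conductivity spectra with tissue metadata, this module
produces the study-shaped result tables: per-group mean +/- SD at the five
analysis frequencies (3, 30, 300, 607, 1000 kHz), the six between-group
conductivity ratios, and the omnibus Kruskal-Wallis comparison.

The ratio table uses the ratio of group means (not the mean of per-patient
ratios): group sizes are unequal and unpaired, so per-patient pairing is
not available in general.  Raw ratios are reported alongside values rounded
to one decimal (half away from zero) for table rendering.

The Kruskal-Wallis H statistic is computed from mid-ranks over the pooled
sample,

    H = 12 / (N (N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2,

tie-corrected by H* = H / (1 - sum(t^3 - t) / (N^3 - N)), and referred to
the chi-square upper tail with k - 1 degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .errors import ConfigurationError, DegenerateDataError, MissingGroupError
from .spectra import ConductivitySpectrum, MeasurementRecord

__all__ = [
    "AnalysisFrequencies",
    "FrequencyPick",
    "GroupSummary",
    "RatioTable",
    "KWResult",
    "pick_frequencies",
    "summarize_groups",
    "ratio_table",
    "kruskal_wallis",
    "significance_report",
    "round_half_away",
]

DEFAULT_TARGETS_KHZ = (3.0, 30.0, 300.0, 607.0, 1000.0)

#: Ratio short-hands: T = tumor, N = normal, C = cirrhotic; "in"/"ex" the
#: in vivo / ex vivo state of the numerator and denominator group.
RATIO_DEFINITIONS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "Tin/Nin": (("tumor", "in_vivo"), ("normal", "in_vivo")),
    "Tin/Tex": (("tumor", "in_vivo"), ("tumor", "ex_vivo")),
    "Tex/Nin": (("tumor", "ex_vivo"), ("normal", "in_vivo")),
    "Tin/Cin": (("tumor", "in_vivo"), ("cirrhotic", "in_vivo")),
    "Tex/Cin": (("tumor", "ex_vivo"), ("cirrhotic", "in_vivo")),
    "Nin/Cin": (("normal", "in_vivo"), ("cirrhotic", "in_vivo")),
}


@dataclass(frozen=True)
class AnalysisFrequencies:
    """The detailed-analysis frequencies, in kHz."""

    targets_khz: tuple[float, ...] = DEFAULT_TARGETS_KHZ

    def __post_init__(self) -> None:
        if not self.targets_khz or any(t <= 0 for t in self.targets_khz):
            raise ConfigurationError("targets must be positive and non-empty")
        object.__setattr__(self, "targets_khz", tuple(float(t) for t in self.targets_khz))


@dataclass(frozen=True)
class FrequencyPick:
    """The grid frequency actually used for one analysis target."""

    target_khz: float
    used_hz: float
    value: float  # sigma at used_hz, S/m


def pick_frequencies(
    spectrum: ConductivitySpectrum,
    targets: AnalysisFrequencies | None = None,
) -> list[FrequencyPick]:
    """Nearest-grid-point lookup for each analysis target.

    Ties between two equidistant grid points break toward the lower
    frequency.  A target outside the grid span is an error (no
    extrapolation).
    """
    targets = targets or AnalysisFrequencies()
    hz = spectrum.grid.hz
    picks = []
    for t_khz in targets.targets_khz:
        t = t_khz * 1e3
        if t < hz[0] or t > hz[-1]:
            raise ConfigurationError(
                f"target {t_khz:g} kHz outside grid span "
                f"[{hz[0] / 1e3:g}, {hz[-1] / 1e3:g}] kHz"
            )
        right = int(np.searchsorted(hz, t, side="left"))
        left = max(right - 1, 0)
        right = min(right, hz.size - 1)
        # low-tie rule: prefer the lower frequency when equidistant
        idx = left if abs(hz[left] - t) <= abs(hz[right] - t) else right
        picks.append(
            FrequencyPick(target_khz=t_khz, used_hz=float(hz[idx]), value=float(spectrum.sigma[idx]))
        )
    return picks


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD of conductivity for one group at one target frequency.

    ``sd`` is None (omitted, not zero) when n < 2, matching blank SD table
    entries for single-case groups.
    """

    tissue_class: str
    state: str
    frequency_khz: float
    n: int
    mean: float
    sd: float | None
    tumor_type: str | None = None

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.tissue_class, self.state)


def summarize_groups(
    records: Sequence[MeasurementRecord],
    targets: AnalysisFrequencies | None = None,
    by_tumor_type: bool = False,
) -> list[GroupSummary]:
    """Sample mean and SD (n-1 denominator) per group per target frequency.

    Groups are (tissue_class, state); cirrhotic parenchyma is its own class
    and never pools with "normal".  With ``by_tumor_type`` only tumor
    records are summarized, split by (state, tumor_type) — the per-type
    table shape.  Record order does not matter.
    """
    if not records:
        raise ConfigurationError("empty cohort: nothing to summarize")
    targets = targets or AnalysisFrequencies()
    values: dict[tuple, dict[float, list[float]]] = {}
    for rec in records:
        if not isinstance(rec.spectrum, ConductivitySpectrum):
            raise ConfigurationError(
                f"record {rec.key} is not calibrated (no conductivity spectrum)"
            )
        if by_tumor_type:
            if rec.tissue_class != "tumor":
                continue
            gkey = (rec.tissue_class, rec.state, rec.tumor_type)
        else:
            gkey = (rec.tissue_class, rec.state)
        slot = values.setdefault(gkey, {t: [] for t in targets.targets_khz})
        for pick in pick_frequencies(rec.spectrum, targets):
            slot[pick.target_khz].append(pick.value)
    if by_tumor_type and not values:
        raise ConfigurationError("no tumor records to summarize by type")
    out: list[GroupSummary] = []
    for gkey in sorted(values):
        for t in targets.targets_khz:
            # sorting makes the result exactly independent of record order
            vals = np.sort(np.array(values[gkey][t]))
            out.append(
                GroupSummary(
                    tissue_class=gkey[0],
                    state=gkey[1],
                    tumor_type=gkey[2] if by_tumor_type else None,
                    frequency_khz=t,
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
                )
            )
    return out


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table-rendering convention)."""
    scale = 10.0**ndigits
    return float(np.copysign(np.floor(np.abs(x) * scale + 0.5) / scale, x))


@dataclass(frozen=True)
class RatioTable:
    """The six between-group conductivity ratios per frequency.

    ``raw`` holds the exact ratio of group means; ``rounded`` the 1-decimal
    rendering.  Both are DataFrames indexed by frequency (kHz) with one
    column per ratio name.
    """

    raw: pd.DataFrame
    rounded: pd.DataFrame


def ratio_table(summaries: Sequence[GroupSummary]) -> RatioTable:
    """Ratio of group means for the six tissue contrasts, per frequency.

    Requires the tumor (in/ex vivo), normal in vivo, and cirrhotic in vivo
    groups at every frequency present in the summaries.
    """
    means: dict[tuple[str, str, float], float] = {}
    freqs: list[float] = []
    for s in summaries:
        if s.tumor_type is not None:
            continue
        means[(s.tissue_class, s.state, s.frequency_khz)] = s.mean
        if s.frequency_khz not in freqs:
            freqs.append(s.frequency_khz)
    needed_groups = {g for pair in RATIO_DEFINITIONS.values() for g in pair}
    raw_rows, rounded_rows = [], []
    for f in freqs:
        missing = sorted(
            f"{cls}/{state}" for (cls, state) in needed_groups if (cls, state, f) not in means
        )
        if missing:
            raise MissingGroupError(
                f"cannot form ratios at {f:g} kHz: missing group(s) {', '.join(missing)}"
            )
        raw = {
            name: means[(num[0], num[1], f)] / means[(den[0], den[1], f)]
            for name, (num, den) in RATIO_DEFINITIONS.items()
        }
        raw_rows.append(raw)
        rounded_rows.append({k: round_half_away(v, 1) for k, v in raw.items()})
    index = pd.Index(freqs, name="frequency_khz")
    return RatioTable(
        raw=pd.DataFrame(raw_rows, index=index),
        rounded=pd.DataFrame(rounded_rows, index=index),
    )


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis omnibus result."""

    h_statistic: float
    degrees_freedom: int
    p_value: float
    tie_corrected: bool


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Rank-based k-group omnibus test with mid-ranks and tie correction.

    Raises :class:`DegenerateDataError` when every pooled value is
    identical (the tie correction denominator vanishes) and
    :class:`ConfigurationError` for fewer than two groups, an empty group,
    or pooled N < 3.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ConfigurationError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ConfigurationError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ConfigurationError("need a pooled sample of at least 3 values")
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical: ranks are degenerate")
    ranks = rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for a in arrays:
        r_mean = ranks[start : start + a.size].mean()
        h += a.size * (r_mean - (n_total + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    has_ties = tie_sum > 0
    if has_ties:
        h /= 1.0 - tie_sum / (n_total**3 - n_total)
    df = len(arrays) - 1
    p = float(chi2.sf(h, df))
    return KWResult(
        h_statistic=float(h),
        degrees_freedom=df,
        p_value=max(p, np.finfo(float).tiny),
        tie_corrected=has_ties,
    )


def significance_report(
    records: Sequence[MeasurementRecord],
    targets: AnalysisFrequencies | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Omnibus Kruskal-Wallis across (tissue_class, state) groups at each
    target frequency; one row per frequency with the significance flag.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    targets = targets or AnalysisFrequencies()
    summaries_needed = summarize_groups(records, targets)  # validates records
    groups_at: dict[float, dict[tuple[str, str], list[float]]] = {
        t: {} for t in targets.targets_khz
    }
    for rec in records:
        gkey = (rec.tissue_class, rec.state)
        for pick in pick_frequencies(rec.spectrum, targets):  # type: ignore[arg-type]
            groups_at[pick.target_khz].setdefault(gkey, []).append(pick.value)
    rows = []
    for t in targets.targets_khz:
        res = kruskal_wallis(list(groups_at[t].values()))
        rows.append(
            {
                "frequency_khz": t,
                "n_groups": res.degrees_freedom + 1,
                "h_statistic": res.h_statistic,
                "degrees_freedom": res.degrees_freedom,
                "p_value": res.p_value,
                "tie_corrected": res.tie_corrected,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
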