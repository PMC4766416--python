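"""Degradation bookkeeping, cell-surface hydrophobicity, and chloride balance.

Percent-removal arithmetic and time-to-threshold interpolation for
substrate concentration time series; the microbial-adherence-to-
hydrocarbon (MATH) hydrophobicity index CSH = (I - F)/I; and the
stoichiometric chloride bound for complete dehalogenation of triclosan
(3 Cl per molecule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import MASS_CL, TCS_N_CL, tcs_molar_mass

__all__ = [
    "TimeSeries",
    "CSHRecord",
    "csh",
    "percent_degraded",
    "time_to_threshold",
    "stoichiometric_chloride",
    "chloride_balance_check",
    "CHLORIDE_MASS_RATIO",
]

SERIES_KINDS = ("tcs_mg_per_L", "od600", "csh")


@dataclass(frozen=True)
class TimeSeries:
    """A sampled trajectory: substrate concentration, OD600, or CSH."""

    time: np.ndarray  # hours, strictly increasing
    value: np.ndarray
    kind: str = "tcs_mg_per_L"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"kind must be one of {SERIES_KINDS}, got {self.kind!r}")
        if self.kind == "tcs_mg_per_L" and t.size and np.any(v < 0):
            raise ValueError("concentrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "value": self.value, "kind": self.kind})


@dataclass(frozen=True)
class CSHRecord:
    """Aqueous-phase OD600 before (I) and after (F) hydrocarbon partitioning."""

    initial_od: float
    final_od: float

    def __post_init__(self) -> None:
        if self.initial_od <= 0:
            raise ValueError(f"initial OD must be > 0, got {self.initial_od}")
        if self.final_od < 0:
            raise ValueError(f"final OD must be >= 0, got {self.final_od}")


def csh(record: CSHRecord) -> float:
    """Cell-surface hydrophobicity (I - F)/I from the MATH assay.

    A final OD above the initial one gives a negative value; it is
    returned but flagged as a measurement anomaly via a warning.
    """
    value = (record.initial_od - record.final_od) / record.initial_od
    if value < 0:
        warnings.warn(
            f"CSH = {value:.4g} < 0 (final OD exceeds initial); "
            "likely a measurement anomaly",
            stacklevel=2,
        )
    return value


def percent_degraded(c0: float, ct: float) -> float:
    """Percent of the initial dose removed: 100*(c0 - ct)/c0, clipped at 0."""
    if c0 <= 0:
        raise ValueError(f"initial concentration must be > 0, got {c0}")
    if ct < 0:
        raise ValueError(f"residual concentration must be >= 0, got {ct}")
    pct = 100.0 * (c0 - ct) / c0
    if pct < 0:
        warnings.warn(
            f"residual {ct} exceeds dose {c0}; percent degraded clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return pct


def time_to_threshold(series: TimeSeries, remaining_fraction: float = 0.01) -> float:
    """First time the concentration falls to remaining_fraction * initial.

    Linear interpolation between sampling points; returns ``math.inf``
    ("not reached") if the series never crosses the threshold.
    """
    if series.time.size == 0:
        raise ValueError("empty time series")
    if not 0.0 <= remaining_fraction <= 1.0:
        raise ValueError(f"remaining_fraction must be in [0, 1], got {remaining_fraction}")
    target = remaining_fraction * series.value[0]
    t, v = series.time, series.value
    if v[0] <= target:
        return float(t[0])
    for i in range(1, t.size):
        if v[i] <= target:
            # crossing within (t[i-1], t[i]]
            if v[i] == v[i - 1]:
                return float(t[i])
            frac = (v[i - 1] - target) / (v[i - 1] - v[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return math.inf


#: mg chloride released per mg triclosan fully dechlorinated
CHLORIDE_MASS_RATIO = TCS_N_CL * MASS_CL / tcs_molar_mass(0)


def stoichiometric_chloride(tcs_conc: float) -> float:
    """Chloride (mg/L) from complete dechlorination of `tcs_conc` mg/L TCS."""
    if tcs_conc < 0:
        raise ValueError(f"tcs_conc must be >= 0, got {tcs_conc}")
    return tcs_conc * CHLORIDE_MASS_RATIO


def chloride_balance_check(
    measured_cl: float, degraded_tcs: float, tol: float = 0.1
) -> str:
    """Compare measured chloride to the dechlorination stoichiometry.

    Returns "consistent" when measured chloride is within a relative
    `tol` of the stoichiometric expectation, otherwise "over-release" or
    "under-release".
    """
    if measured_cl < 0 or degraded_tcs < 0:
        raise ValueError("inputs must be >= 0")
    expected = stoichiometric_chloride(degraded_tcs)
    if expected == 0:
        return "consistent" if measured_cl == 0 else "over-release"
    rel = (measured_cl - expected) / expected
    if abs(rel) <= tol:
        return "consistent"
    return "over-release" if rel > 0 else "under-release"
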