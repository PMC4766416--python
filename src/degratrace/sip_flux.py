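"""Stable-isotope-probing arithmetic for 13C-labeled PLFA biomarkers.

Tracks how much of a 13C-labeled substrate dose ends up in individual
phospholipid fatty acids.  The chain of definitions:

    R = (delta/1000 + 1) * R_std          (delta notation -> isotope ratio)
    F = R / (R + 1)                        (ratio -> 13C atom fraction)
    excess_i = (F_lab,i - F_unlab,i) * [PLFA_i]_lab
    % of added = 100 * excess_i / 13C_added
    % distribution = 100 * excess_i / sum_j excess_j

Concentrations are mg C per kg of solution throughout; delta values are
per mille against a 13C/12C reference standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MASS_13C, tcs_molar_mass

__all__ = [
    "IsotopeStandard",
    "VPDB",
    "VPDB_CONVENTIONAL",
    "PLFARecord",
    "IncorporationResult",
    "NoLabelDetectedError",
    "delta_to_ratio",
    "ratio_to_fraction",
    "fraction_to_ratio",
    "fraction_to_delta",
    "delta_to_fraction",
    "excess_13c",
    "incorporation_summary",
    "added_13c_from_dose",
    "headspace_pct13c",
]


class NoLabelDetectedError(ValueError):
    """No PLFA shows positive 13C excess; a distribution is undefined."""


@dataclass(frozen=True)
class IsotopeStandard:
    """A 13C/12C reference ratio for delta notation."""

    r_std: float

    def __post_init__(self) -> None:
        if self.r_std <= 0:
            raise ValueError(f"reference ratio must be > 0, got {self.r_std}")


#: Pee Dee Belemnite ratio as rounded in the study this package reproduces
VPDB = IsotopeStandard(0.0112)
#: the conventional VPDB value, selectable where higher precision matters
VPDB_CONVENTIONAL = IsotopeStandard(0.0111802)


def delta_to_ratio(delta: float, standard: IsotopeStandard = VPDB) -> float:
    """13C/12C ratio from a per-mille delta value."""
    delta = float(delta)
    if delta <= -1000.0:
        raise ValueError(
            f"delta must be > -1000 permil (atom fraction in [0,1)), got {delta}"
        )
    return (delta / 1000.0 + 1.0) * standard.r_std


def ratio_to_fraction(r: float) -> float:
    """13C atom fraction F = R/(R+1) from the 13C/12C ratio."""
    r = float(r)
    if r < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {r}")
    return r / (r + 1.0)


def fraction_to_ratio(f: float) -> float:
    f = float(f)
    if not 0.0 <= f < 1.0:
        raise ValueError(f"atom fraction must be in [0, 1), got {f}")
    return f / (1.0 - f)


def fraction_to_delta(f: float, standard: IsotopeStandard = VPDB) -> float:
    """Per-mille delta value from a 13C atom fraction."""
    return (fraction_to_ratio(f) / standard.r_std - 1.0) * 1000.0


def delta_to_fraction(delta: float, standard: IsotopeStandard = VPDB) -> float:
    return ratio_to_fraction(delta_to_ratio(delta, standard))


@dataclass(frozen=True)
class PLFARecord:
    """One PLFA's carbon pool and its delta13C pair (labeled vs control).

    conc_labeled is the PLFA carbon concentration in the labeled culture,
    mg C per kg of solution; delta values are per mille.
    """

    name: str
    conc_labeled: float
    delta_labeled: float
    delta_unlabeled: float

    def __post_init__(self) -> None:
        if self.conc_labeled < 0:
            raise ValueError(f"{self.name}: conc_labeled must be >= 0")
        for d in (self.delta_labeled, self.delta_unlabeled):
            if d <= -1000.0:
                raise ValueError(f"{self.name}: delta {d} out of range (<= -1000)")


def excess_13c(record: PLFARecord, standard: IsotopeStandard = VPDB) -> float:
    """Excess 13C in one PLFA, mg C per kg: (F_lab - F_unlab) * conc.

    A negative value (labeled culture lighter than the control) is
    returned as-is; callers treating it as assimilated label should flag
    it as a measurement anomaly.
    """
    f_lab = delta_to_fraction(record.delta_labeled, standard)
    f_unlab = delta_to_fraction(record.delta_unlabeled, standard)
    return (f_lab - f_unlab) * record.conc_labeled


@dataclass(frozen=True)
class IncorporationResult:
    """Per-PLFA and total 13C incorporation accounting.

    pct_distribution is computed over PLFAs with positive excess only
    (NaN for the others) and sums to 100 over that subset.
    """

    names: tuple[str, ...]
    excess: np.ndarray  # mg 13C per kg, may contain negatives
    pct_of_added: np.ndarray  # percent of the added 13C dose
    pct_distribution: np.ndarray  # percent of total labeled-PLFA 13C
    negative_flags: np.ndarray  # True where excess < 0
    total_excess: float
    total_pct_of_added: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plfa": list(self.names),
                "excess_13c_mg_per_kg": self.excess,
                "pct_of_added_13c": self.pct_of_added,
                "pct_distribution": self.pct_distribution,
                "negative_excess": self.negative_flags,
            }
        )


def incorporation_summary(
    records: list[PLFARecord],
    added_13c: float,
    standard: IsotopeStandard = VPDB,
) -> IncorporationResult:
    """Summarize 13C incorporation across PLFAs against the added label.

    Parameters
    ----------
    records
        Per-PLFA measurements.
    added_13c
        13C added with the substrate dose, mg 13C per kg solution.

    Notes
    -----
    PLFAs with negative excess (isotopically lighter than the control)
    are retained in the per-PLFA output with a flag, but excluded from
    the distribution denominator.  If no PLFA has positive excess a
    :class:`NoLabelDetectedError` is raised.
    """
    if added_13c <= 0:
        raise ValueError(f"added_13c must be > 0, got {added_13c}")
    if not records:
        raise ValueError("at least one PLFA record is required")

    names = tuple(r.name for r in records)
    exc = np.array([excess_13c(r, standard) for r in records])
    neg = exc < 0
    warns: list[str] = []
    if neg.any():
        bad = [names[i] for i in np.flatnonzero(neg)]
        warns.append(
            f"negative 13C excess in {bad}; excluded from distribution denominator"
        )
        warnings.warn(warns[-1], stacklevel=2)

    pct_added = 100.0 * exc / added_13c
    pos_total = float(exc[~neg].sum())
    if pos_total <= 0:
        raise NoLabelDetectedError(
            "no PLFA shows positive 13C excess; distribution undefined "
            "(per-PLFA pct_of_added values are still computable)"
        )
    dist = np.where(neg, np.nan, 100.0 * exc / pos_total)

    return IncorporationResult(
        names=names,
        excess=exc,
        pct_of_added=pct_added,
        pct_distribution=dist,
        negative_flags=neg,
        total_excess=float(exc.sum()),
        total_pct_of_added=float(pct_added.sum()),
        warnings=tuple(warns),
    )


def added_13c_from_dose(
    tcs_conc: float, n_labeled_positions: int = 12
) -> float:
    """Mass of 13C delivered per liter by a labeled-triclosan dose.

    For a uniformly ring-labeled 13C12 substrate at `tcs_conc` mg/L, the
    13C mass is the dose times the 13C mass fraction of the labeled
    molecule: tcs_conc * n * m(13C) / M(13Cn-TCS).
    """
    if tcs_conc < 0:
        raise ValueError(f"tcs_conc must be >= 0, got {tcs_conc}")
    m_total = tcs_molar_mass(n_labeled_positions)  # validates n
    return tcs_conc * n_labeled_positions * MASS_13C / m_total


def headspace_pct13c(
    mol_13co2: float, mol_12co2: float, atom_percent: bool = False
) -> float:
    """Headspace CO2 label percentage.

    Default is the ratio convention 100 * 13CO2/12CO2; `atom_percent`
    switches to 100 * 13CO2/(13CO2 + 12CO2).
    """
    if mol_13co2 < 0 or mol_12co2 < 0:
        raise ValueError("amounts must be >= 0")
    if mol_13co2 == 0 and mol_12co2 == 0:
        raise ZeroDivisionError("both CO2 amounts are zero; ratio undefined")
    if atom_percent:
        return 100.0 * mol_13co2 / (mol_13co2 + mol_12co2)
    if mol_12co2 == 0:
        raise ZeroDivisionError("12CO2 amount is zero; ratio percent undefined")
    return 100.0 * mol_13co2 / mol_12co2
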