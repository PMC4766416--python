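"""Synthetic data generators mirroring the statistical structure of the
triclosan-degradation experiments.

Three generators, each the algebraic inverse of the corresponding
analysis so that round-trip (generate -> analyze) recovery is exact in
the noise-free case:

* a quadratic response surface evaluated on a Box-Behnken design with
  Gaussian response noise;
* a 13C-PLFA labeling experiment where known fractions of the added
  label enter each lipid pool, converted back to delta13C readings;
* degradation / growth / hydrophobicity trajectories with a logistic
  substrate decay, logistic growth, and a beta-shaped unimodal CSH
  pulse.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .doe_rsm import DEFAULT_FACTORS, DesignMatrix, ResponseTable, _model_columns, FULL_TERMS
from .sip_flux import (
    VPDB,
    IsotopeStandard,
    PLFARecord,
    added_13c_from_dose,
    delta_to_fraction,
    fraction_to_delta,
)
from .kinetics_csh import TimeSeries

__all__ = [
    "SurfaceSpec",
    "SIPSpec",
    "CurveSpec",
    "InfeasibleSpecError",
    "simulate_bbd_response",
    "simulate_sip_experiment",
    "simulate_degradation_csh",
]


class InfeasibleSpecError(ValueError):
    """The requested label load exceeds what an isotope pool can hold."""


# coefficients of the fitted Table-style surface, used as a realistic default
_DEFAULT_SURFACE_COEF = (
    5.0, 1.515, 1.5313, 0.0362, -1.7363, -1.8087, -0.4338, 1.165, -0.02, 0.0475
)


@dataclass(frozen=True)
class SurfaceSpec:
    """True quadratic surface for design-of-experiments simulations.

    `coef` follows the canonical term order: intercept, 3 linear,
    3 quadratic, 3 interactions (x1x2, x1x3, x2x3).
    """

    coef: tuple[float, ...] = _DEFAULT_SURFACE_COEF
    noise_sd: float = 0.1  # mg/L
    dose: float = 5.0  # mg/L ceiling
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.coef) != 10:
            raise ValueError(f"need 10 coefficients, got {len(self.coef)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")


def simulate_bbd_response(
    spec: SurfaceSpec, design: DesignMatrix, truncate: bool = False
) -> ResponseTable:
    """Evaluate the true surface on the design and add Gaussian noise.

    `truncate` clips responses to [0, dose] (degradation cannot exceed
    the dose); off by default because clipping biases coefficient
    recovery.
    """
    rng = np.random.default_rng(spec.seed)
    X = _model_columns(design.runs, FULL_TERMS)
    y = X @ np.asarray(spec.coef, dtype=float)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    if truncate:
        y = np.clip(y, 0.0, spec.dose)
    return ResponseTable(design=design, response=y)


# the five PLFA markers of the degrader strain, with the incorporation
# fractions reported for them and typical lipid carbon pool sizes
_DEFAULT_PLFAS = ("14:0 2OH", "16:0", "sum in feature 3", "sum in feature 8", "16:1 w5c")
_DEFAULT_FRACTIONS = (0.0699, 0.0837, 0.1384, 0.159, 0.1648)
_DEFAULT_POOLS = (0.8, 2.5, 1.6, 2.0, 1.2)  # mg C per kg solution


@dataclass(frozen=True)
class SIPSpec:
    """True parameters of a 13C-PLFA labeling experiment.

    `fractions[i]` is the fraction of the added 13C that ends up in
    PLFA i; `pools` are the lipid carbon concentrations in the labeled
    culture (mg C/kg).  `added_13c` defaults to the 13C delivered by a
    5 mg/L dose of uniformly 13C12-labeled triclosan, assuming solution
    density 1 kg/L.
    """

    names: tuple[str, ...] = _DEFAULT_PLFAS
    pools: tuple[float, ...] = _DEFAULT_POOLS
    fractions: tuple[float, ...] = _DEFAULT_FRACTIONS
    added_13c: float = added_13c_from_dose(5.0)  # mg 13C per kg
    baseline_delta: float = -25.0  # permil, heterotroph biomass
    delta_noise_sd: float = 0.3  # permil
    seed: int = 0
    standard: IsotopeStandard = VPDB

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.pools) == len(self.fractions) == n):
            raise ValueError("names, pools and fractions must align")
        if any(p <= 0 for p in self.pools):
            raise ValueError("pools must be > 0")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be >= 0")
        if sum(self.fractions) > 1.0 + 1e-12:
            raise ValueError("fractions must sum to <= 1")
        if self.added_13c <= 0:
            raise ValueError("added_13c must be > 0")
        if self.delta_noise_sd < 0:
            raise ValueError("delta_noise_sd must be >= 0")


def simulate_sip_experiment(spec: SIPSpec) -> tuple[list[PLFARecord], float]:
    """Generate PLFA delta13C readings from known incorporation fractions.

    For each PLFA the implied excess 13C is fraction * added_13c; the
    labeled atom fraction is the natural-abundance baseline plus
    excess/pool, converted back to delta notation.  Gaussian delta noise
    (sd `delta_noise_sd`) is applied independently to the labeled and
    control readings.

    Returns the records and the added 13C (mg/kg) to feed into
    :func:`degratrace.sip_flux.incorporation_summary`.
    """
    rng = np.random.default_rng(spec.seed)
    f_base = delta_to_fraction(spec.baseline_delta, spec.standard)
    records = []
    for name, pool, frac in zip(spec.names, spec.pools, spec.fractions):
        excess = frac * spec.added_13c
        f_lab = f_base + excess / pool
        if f_lab >= 1.0:
            raise InfeasibleSpecError(
                f"PLFA {name!r}: implied labeled atom fraction {f_lab:.3f} >= 1; "
                f"label ({excess:.3g} mg/kg) exceeds pool capacity ({pool} mg C/kg)"
            )
        d_lab = fraction_to_delta(f_lab, spec.standard)
        d_unlab = spec.baseline_delta
        if spec.delta_noise_sd > 0:
            d_lab += rng.normal(0.0, spec.delta_noise_sd)
            d_unlab += rng.normal(0.0, spec.delta_noise_sd)
        records.append(
            PLFARecord(
                name=name,
                conc_labeled=pool,
                delta_labeled=d_lab,
                delta_unlabeled=d_unlab,
            )
        )
    return records, spec.added_13c


@dataclass(frozen=True)
class CurveSpec:
    """Shapes of the degradation / growth / hydrophobicity trajectories.

    The substrate follows a logistic decay from `dose` (exact at t=0)
    reaching `residual_fraction` of the dose at `completion_time`; OD
    grows logistically to `od_plateau`; CSH is a smooth unimodal
    beta-shaped pulse, zero at t=0, peaking at (`csh_peak_time`,
    `csh_peak`).  Defaults reflect a 5 mg/L dose mineralized within
    72 h with peak hydrophobicity 0.76 at 48 h.
    """

    dose: float = 5.0  # mg/L
    completion_time: float = 72.0  # h
    residual_fraction: float = 0.005
    csh_peak: float = 0.76
    csh_peak_time: float = 48.0  # h
    od_plateau: float = 0.9
    sampling_times: tuple[float, ...] = tuple(float(t) for t in range(0, 97, 8))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.completion_time <= 0:
            raise ValueError("dose and completion_time must be > 0")
        if not 0 < self.residual_fraction < 1:
            raise ValueError("residual_fraction must be in (0, 1)")
        times = tuple(float(t) for t in self.sampling_times)
        object.__setattr__(self, "sampling_times", times)
        if not times or times[0] != 0.0:
            raise ValueError("sampling must start at t=0")
        if not times[0] <= self.csh_peak_time <= times[-1]:
            raise ValueError("CSH peak time must lie within the sampling window")


def _logistic_decay(t: np.ndarray, dose: float, t_end: float, residual: float) -> np.ndarray:
    # scaled logistic with midpoint at t_end/2; the scaling makes the
    # value exactly `dose` at t=0 and exactly `residual*dose` at t_end
    k = 2.0 * math.log(1.0 / residual) / t_end
    s = 1.0 / (1.0 + np.exp(k * (t - t_end / 2.0)))
    s0 = 1.0 / (1.0 + math.exp(-k * t_end / 2.0))
    return dose * s / s0


def _beta_pulse(t: np.ndarray, peak: float, t_peak: float, t_end: float, shape: float = 4.0) -> np.ndarray:
    x = np.clip(t / t_end, 0.0, 1.0)
    r = t_peak / t_end
    p, q = shape * r, shape * (1.0 - r)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = peak * (x / r) ** p * ((1.0 - x) / (1.0 - r)) ** q
    return np.where(np.isfinite(val), val, 0.0)


def simulate_degradation_csh(spec: CurveSpec) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Generate (substrate, OD600, CSH) trajectories on a shared grid."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times, dtype=float)

    tcs = _logistic_decay(t, spec.dose, spec.completion_time, spec.residual_fraction)
    k_od = 8.0 / spec.completion_time  # growth completes alongside degradation
    od = spec.od_plateau / (1.0 + np.exp(-k_od * (t - spec.completion_time / 2.0)))
    cshv = _beta_pulse(t, spec.csh_peak, spec.csh_peak_time, t[-1])

    if spec.noise_sd > 0:
        tcs = np.clip(tcs + rng.normal(0, spec.noise_sd * spec.dose, t.shape), 0, None)
        od = np.clip(od + rng.normal(0, spec.noise_sd * spec.od_plateau, t.shape), 0, None)
        cshv = np.clip(cshv + rng.normal(0, spec.noise_sd, t.shape), 0, 1)

    return (
        TimeSeries(time=t, value=tcs, kind="tcs_mg_per_L"),
        TimeSeries(time=t, value=od, kind="od600"),
        TimeSeries(time=t, value=cshv, kind="csh"),
    )
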