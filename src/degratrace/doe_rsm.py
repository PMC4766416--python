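"""Box-Behnken designs and second-order response-surface analysis.

Implements the design-of-experiments workflow used to optimize microbial
triclosan degradation: generating a three-factor Box-Behnken design,
coding factor levels, fitting the full quadratic polynomial

    Y = b0 + sum_i bi*xi + sum_i bii*xi^2 + sum_{i<j} bij*xi*xj

by ordinary least squares on coded levels, testing coefficient
significance, pruning non-significant interactions, and locating and
classifying the stationary point of the fitted surface (canonical
analysis).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FactorDef",
    "DesignMatrix",
    "ResponseTable",
    "QuadraticModel",
    "StationaryPoint",
    "UnsupportedDesignError",
    "SingularDesignError",
    "generate_box_behnken",
    "code_value",
    "decode_value",
    "fit_quadratic",
    "prune_interactions",
    "stationary_point",
    "predict",
]


class UnsupportedDesignError(ValueError):
    """Raised for factor counts the design generator does not support."""


class SingularDesignError(ValueError):
    """Raised when the model matrix is rank deficient."""


@dataclass(frozen=True)
class FactorDef:
    """A physical factor with its low / center / high levels.

    Coding maps low -> -1, center -> 0, high -> +1.  The map is affine
    from (low, high) when the center is the midpoint; otherwise it is
    piecewise affine below and above the center (a warning is emitted
    at construction since an off-midpoint center is unusual).
    """

    name: str
    low: float
    center: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: need low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )
        mid = 0.5 * (self.low + self.high)
        if not np.isclose(self.center, mid, rtol=0.0, atol=1e-9 * (self.high - self.low)):
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"of [{self.low}, {self.high}]; coding is piecewise affine",
                stacklevel=3,
            )


# the three factors of the triclosan-degradation optimization
TEMPERATURE = FactorDef("temperature", 20.0, 30.0, 40.0, "degC")
PH = FactorDef("pH", 5.0, 7.0, 9.0, "")
BIOMASS = FactorDef("biomass", 0.1, 0.2, 0.3, "g/L")
DEFAULT_FACTORS = (TEMPERATURE, PH, BIOMASS)


def code_value(factor: FactorDef, physical: float) -> float:
    """Map a physical value onto the coded scale (low/center/high -> -1/0/+1).

    Values beyond the factor range are extrapolated and a warning is
    emitted.
    """
    physical = float(physical)
    if physical >= factor.center:
        coded = (physical - factor.center) / (factor.high - factor.center)
    else:
        coded = (physical - factor.center) / (factor.center - factor.low)
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"factor {factor.name!r}: physical value {physical} codes to "
            f"{coded:.4g}, outside [-1, 1]",
            stacklevel=2,
        )
    return coded


def decode_value(factor: FactorDef, coded: float) -> float:
    """Inverse of :func:`code_value`: coded -1/0/+1 -> low/center/high."""
    coded = float(coded)
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"factor {factor.name!r}: coded value {coded} is outside [-1, 1]",
            stacklevel=2,
        )
    if coded >= 0.0:
        return factor.center + coded * (factor.high - factor.center)
    return factor.center + coded * (factor.center - factor.low)


@dataclass(frozen=True)
class DesignMatrix:
    """Coded runs of a designed experiment."""

    factors: tuple[FactorDef, ...]
    runs: np.ndarray  # shape (n_runs, n_factors), values in {-1, 0, +1}

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=float)
        object.__setattr__(self, "runs", runs)
        if runs.ndim != 2 or runs.shape[1] != len(self.factors):
            raise ValueError("runs must be (n_runs, n_factors)")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i + 1}": self.runs[:, i] for i in range(self.n_factors)}
        df = pd.DataFrame(cols)
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        return df

    def decoded_frame(self) -> pd.DataFrame:
        """Runs on the physical scale, one column per factor name."""
        data = {
            f.name: [decode_value(f, c) for c in self.runs[:, i]]
            for i, f in enumerate(self.factors)
        }
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ResponseTable:
    """A design plus one measured response per run."""

    design: DesignMatrix
    response: np.ndarray  # mg/L degraded, one value per run

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", resp)
        if resp.shape != (self.design.n_runs,):
            raise ValueError(
                f"response length {resp.shape} does not match "
                f"{self.design.n_runs} runs"
            )

    def to_frame(self) -> pd.DataFrame:
        df = self.design.to_frame()
        df["response"] = self.response
        return df


def generate_box_behnken(
    factors: list[FactorDef] | tuple[FactorDef, ...],
    n_center: int = 3,
) -> DesignMatrix:
    """Generate a three-factor Box-Behnken design.

    The 12 edge runs enumerate all (+-1, +-1) combinations over the three
    factor pairs with the remaining factor at 0, in canonical pair-block
    order ((x1,x2) block, (x1,x3) block, (x2,x3) block); `n_center`
    all-zero center runs follow.

    Parameters
    ----------
    factors
        Exactly three factor definitions.
    n_center
        Number of replicated center points (>= 1).
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"Box-Behnken generation supports exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")

    rows = []
    for i, j in itertools.combinations(range(3), 2):
        for a, b in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * n_center)
    return DesignMatrix(factors=factors, runs=np.asarray(rows))


# ---------------------------------------------------------------------------
# model fitting


#: canonical term order of the full second-order model for 3 factors
FULL_TERMS = ("const", "x1", "x2", "x3", "x1^2", "x2^2", "x3^2", "x1*x2", "x1*x3", "x2*x3")


def _model_columns(runs: np.ndarray, terms: tuple[str, ...]) -> np.ndarray:
    """Build the model matrix for the given term names from coded runs."""
    k = runs.shape[1]
    cols = []
    for term in terms:
        if term == "const":
            cols.append(np.ones(runs.shape[0]))
        elif "*" in term:
            a, b = term.split("*")
            i, j = int(a[1:]) - 1, int(b[1:]) - 1
            cols.append(runs[:, i] * runs[:, j])
        elif term.endswith("^2"):
            i = int(term[1:-2]) - 1
            cols.append(runs[:, i] ** 2)
        else:
            i = int(term[1:]) - 1
            if i >= k:
                raise ValueError(f"term {term} exceeds {k} factors")
            cols.append(runs[:, i])
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """A fitted second-order polynomial on coded factor levels.

    `terms` lists the retained model terms in canonical order; the
    coefficient arrays are aligned with it.  Interaction terms may be
    absent after pruning; linear and quadratic terms are always present.
    """

    factors: tuple[FactorDef, ...]
    terms: tuple[str, ...]
    coef: np.ndarray
    stderr: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    df_resid: int
    n_runs: int
    response_name: str = "response"

    def __post_init__(self) -> None:
        for name in ("coef", "stderr", "tvalues", "pvalues"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not len(self.terms) == len(self.coef):
            raise ValueError("terms/coefficients length mismatch")

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "coef": self.coef,
                "stderr": self.stderr,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def __getitem__(self, term: str) -> float:
        """Coefficient of a term by name; 0.0 for a pruned interaction."""
        if term in self.terms:
            return float(self.coef[self.terms.index(term)])
        if "*" in term:
            return 0.0
        raise KeyError(term)

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if "*" in t)

    def curvature_matrix(self) -> np.ndarray:
        """Symmetric matrix B with b_ii on the diagonal and b_ij/2 off it."""
        k = self.n_factors
        B = np.zeros((k, k))
        for i in range(k):
            B[i, i] = self[f"x{i + 1}^2"]
            for j in range(i + 1, k):
                B[i, j] = B[j, i] = self[f"x{i + 1}*x{j + 1}"] / 2.0
        return B

    def linear_vector(self) -> np.ndarray:
        return np.array([self[f"x{i + 1}"] for i in range(self.n_factors)])


def fit_quadratic(table: ResponseTable, terms: tuple[str, ...] = FULL_TERMS) -> QuadraticModel:
    """Fit the second-order polynomial by ordinary least squares.

    Per-coefficient t tests use the residual variance of the fit; R^2 is
    1 - SSE/SST.  Raises :class:`SingularDesignError` if the model matrix
    is rank deficient, naming the collinear terms.
    """
    runs = table.design.runs
    y = table.response
    if len(y) < len(terms):
        raise SingularDesignError(
            f"{len(y)} runs cannot estimate {len(terms)} coefficients"
        )
    X = _model_columns(runs, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending terms by incremental rank growth
        bad = []
        r = 0
        for c in range(X.shape[1]):
            new = np.linalg.matrix_rank(X[:, : c + 1])
            if new == r:
                bad.append(terms[c])
            r = new
        raise SingularDesignError(f"design is rank deficient; collinear terms: {bad}")
    res = sm.OLS(y, X).fit()
    return QuadraticModel(
        factors=table.design.factors,
        terms=tuple(terms),
        coef=res.params,
        stderr=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
        n_runs=len(y),
    )


def prune_interactions(
    model: QuadraticModel, table: ResponseTable, alpha: float = 0.05
) -> QuadraticModel:
    """Backward-eliminate non-significant interaction terms.

    Iteratively removes the interaction with the largest p value >= alpha
    and refits, until all remaining interactions are significant.  Linear
    and quadratic terms are never removed, mirroring the practice of
    retaining non-significant main effects of designed factors.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    current = model
    while True:
        inters = [(t, current.pvalues[current.terms.index(t)]) for t in current.interaction_terms]
        removable = [(t, p) for t, p in inters if p >= alpha]
        if not removable:
            return current
        worst = max(removable, key=lambda tp: tp[1])[0]
        new_terms = tuple(t for t in current.terms if t != worst)
        current = fit_quadratic(table, terms=new_terms)


def predict(
    model: QuadraticModel,
    point: np.ndarray,
    clamp: tuple[float, float] | None = None,
) -> float:
    """Evaluate the fitted polynomial at a coded point.

    `clamp=(lo, hi)` optionally clips the prediction (degradation cannot
    exceed the dose); off by default.
    """
    point = np.atleast_2d(np.asarray(point, dtype=float))
    if point.shape[1] != model.n_factors:
        raise ValueError(
            f"point has {point.shape[1]} coordinates, model has {model.n_factors} factors"
        )
    X = _model_columns(point, model.terms)
    val = float((X @ model.coef)[0])
    if clamp is not None:
        val = float(np.clip(val, *clamp))
    return val


@dataclass(frozen=True)
class StationaryPoint:
    """Stationary point of a fitted quadratic surface.

    Coordinates are reported for the free factors only; factors held
    fixed during the canonical analysis appear in `fixed`.
    """

    free_factors: tuple[str, ...]
    coded: np.ndarray | None
    physical: dict[str, float] | None
    predicted: float | None
    nature: str  # maximum | minimum | saddle | degenerate
    eigenvalues: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)
    message: str = ""


def stationary_point(
    model: QuadraticModel,
    fixed: dict[str, float] | None = None,
    tol_rel: float = 1e-8,
    tol_abs: float = 1e-10,
) -> StationaryPoint:
    """Locate and classify the stationary point of the fitted surface.

    Solves grad Y = 0, i.e. 2 B x = -b, over the free factors, with any
    `fixed` coded values substituted into the surface first.  The nature
    is read off the eigenvalues of the restricted curvature matrix B:
    all < -tol -> maximum, all > +tol -> minimum, mixed -> saddle, any
    |eigenvalue| <= tol -> degenerate (ridge analysis recommended).

    `fixed` maps factor names (or "x1"-style labels) to coded values.
    """
    fixed = dict(fixed or {})
    k = model.n_factors
    names = [f.name for f in model.factors]
    fixed_idx: dict[int, float] = {}
    for key, val in fixed.items():
        if key in names:
            i = names.index(key)
        elif key.startswith("x") and key[1:].isdigit():
            i = int(key[1:]) - 1
        else:
            raise KeyError(f"unknown factor {key!r}")
        fixed_idx[i] = float(val)

    free = [i for i in range(k) if i not in fixed_idx]
    if not free:
        raise ValueError("at least one factor must remain free")

    B = model.curvature_matrix()
    b = model.linear_vector()
    # substitute fixed coordinates: restricted linear term picks up cross terms
    b_free = b[free].copy()
    for fi, fval in fixed_idx.items():
        b_free += 2.0 * B[np.ix_(free, [fi])].ravel() * fval
    B_free = B[np.ix_(free, free)]

    eigvals = np.linalg.eigvalsh(B_free)
    tol = max(tol_rel * float(np.max(np.abs(eigvals), initial=0.0)), tol_abs)

    if np.any(np.abs(eigvals) <= tol):
        return StationaryPoint(
            free_factors=tuple(names[i] for i in free),
            coded=None,
            physical=None,
            predicted=None,
            nature="degenerate",
            eigenvalues=eigvals,
            fixed={names[i]: v for i, v in fixed_idx.items()},
            message=(
                "curvature matrix is near singular; the surface has a ridge "
                "or flat direction — consider ridge analysis"
            ),
        )

    x_free = np.linalg.solve(2.0 * B_free, -b_free)
    full = np.zeros(k)
    full[free] = x_free
    for fi, fval in fixed_idx.items():
        full[fi] = fval
    pred = predict(model, full)

    if np.all(eigvals < -tol):
        nature = "maximum"
    elif np.all(eigvals > tol):
        nature = "minimum"
    else:
        nature = "saddle"

    physical = {
        names[i]: decode_value(model.factors[i], full[i]) for i in free
    }
    return StationaryPoint(
        free_factors=tuple(names[i] for i in free),
        coded=x_free,
        physical=physical,
        predicted=pred,
        nature=nature,
        eigenvalues=eigvals,
        fixed={names[i]: v for i, v in fixed_idx.items()},
    )
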