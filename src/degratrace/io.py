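"""CSV readers, factor-config parsing, and analysis-report serialization.

CSV dialects (comma separator, dot decimal, UTF-8, header required):

* design/response: ``run,x1,x2,x3,response`` with coded levels in
  {-1, 0, 1};
* PLFA: ``plfa,conc_labeled_mgC_per_kg,delta13c_labeled_permil,
  delta13c_unlabeled_permil``;
* time series: ``time_h,value,kind`` with kind in
  {tcs_mg_per_L, od600, csh}.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .doe_rsm import (
    DEFAULT_FACTORS,
    DesignMatrix,
    FactorDef,
    QuadraticModel,
    ResponseTable,
    StationaryPoint,
)
from .kinetics_csh import SERIES_KINDS, TimeSeries
from .sip_flux import IncorporationResult, PLFARecord

__all__ = [
    "SchemaError",
    "ParseError",
    "DomainError",
    "read_design_response",
    "read_plfa_table",
    "read_timeseries",
    "read_factors_config",
    "write_design_response",
    "RunConfig",
    "AnalysisReport",
    "write_report",
]


class SchemaError(ValueError):
    """Input file lacks a required column or is empty."""


class ParseError(ValueError):
    """A cell could not be parsed; message carries row and column."""


class DomainError(ValueError):
    """A parsed value is outside its allowed domain."""


def _load_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    out = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df[col]):
        try:
            out[i] = float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric value {raw!r} in column {col!r}, data row {i + 1}"
            ) from None
    return out


def read_design_response(
    path: str | Path, factors: tuple[FactorDef, ...] = DEFAULT_FACTORS
) -> ResponseTable:
    """Read a coded design + response CSV into a :class:`ResponseTable`."""
    df = _load_csv(path, ("run", "x1", "x2", "x3", "response"))
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    coded = np.column_stack([_numeric(df, c, path) for c in ("x1", "x2", "x3")])
    for (r, c), v in np.ndenumerate(coded):
        if v not in (-1.0, 0.0, 1.0):
            raise DomainError(
                f"{path}: coded level {v} outside {{-1, 0, 1}} in column x{c + 1}, "
                f"data row {r + 1}"
            )
    response = _numeric(df, "response", path)
    design = DesignMatrix(factors=tuple(factors), runs=coded)
    return ResponseTable(design=design, response=response)


def write_design_response(table: ResponseTable, path: str | Path) -> None:
    df = table.to_frame()
    df["run"] = df["run"].astype(int)
    for c in ("x1", "x2", "x3"):
        df[c] = df[c].astype(int)
    df.to_csv(path, index=False)


def read_plfa_table(path: str | Path) -> list[PLFARecord]:
    """Read a PLFA measurement CSV into records."""
    cols = (
        "plfa",
        "conc_labeled_mgC_per_kg",
        "delta13c_labeled_permil",
        "delta13c_unlabeled_permil",
    )
    df = _load_csv(path, cols)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    conc = _numeric(df, cols[1], path)
    d_lab = _numeric(df, cols[2], path)
    d_unlab = _numeric(df, cols[3], path)
    return [
        PLFARecord(name=str(n), conc_labeled=c, delta_labeled=dl, delta_unlabeled=du)
        for n, c, dl, du in zip(df["plfa"], conc, d_lab, d_unlab)
    ]


def write_plfa_table(records: list[PLFARecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plfa": [r.name for r in records],
            "conc_labeled_mgC_per_kg": [r.conc_labeled for r in records],
            "delta13c_labeled_permil": [r.delta_labeled for r in records],
            "delta13c_unlabeled_permil": [r.delta_unlabeled for r in records],
        }
    ).to_csv(path, index=False)


def read_timeseries(path: str | Path) -> dict[str, TimeSeries]:
    """Read a time-series CSV; returns one series per kind tag found."""
    df = _load_csv(path, ("time_h", "value", "kind"))
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    t = _numeric(df, "time_h", path)
    v = _numeric(df, "value", path)
    out: dict[str, TimeSeries] = {}
    for kind in pd.unique(df["kind"]):
        if kind not in SERIES_KINDS:
            raise DomainError(f"{path}: unknown series kind {kind!r}")
        mask = (df["kind"] == kind).to_numpy()
        order = np.argsort(t[mask], kind="stable")
        out[kind] = TimeSeries(time=t[mask][order], value=v[mask][order], kind=kind)
    return out


def write_timeseries(series: list[TimeSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def read_factors_config(path: str | Path) -> tuple[FactorDef, ...]:
    """Read factor definitions from a YAML/key-value config.

    Expected layout::

        factors:
          - {name: temperature, low: 20, center: 30, high: 40, units: degC}
          - ...
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "factors" not in cfg:
        raise SchemaError(f"{path}: expected a top-level 'factors' list")
    factors = []
    for i, entry in enumerate(cfg["factors"]):
        try:
            factors.append(
                FactorDef(
                    name=str(entry["name"]),
                    low=float(entry["low"]),
                    center=float(entry["center"]),
                    high=float(entry["high"]),
                    units=str(entry.get("units", "")),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: factor {i}: missing key {exc}") from None
    return tuple(factors)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one combined analysis run."""

    alpha: float = 0.05
    r_std: float = 0.0112
    dose: float = 5.0
    completion_threshold: float = 0.01
    chloride_tol: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class AnalysisReport:
    """Combined machine-readable results of the analysis stages."""

    config: dict[str, Any] = field(default_factory=dict)
    rsm: dict[str, Any] | None = None
    sip: dict[str, Any] | None = None
    degradation: dict[str, Any] | None = None
    warnings: list[str] = field(default_factory=list)
    version: str = ""


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, float) and math.isinf(obj):
        return "not reached"
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def model_to_dict(model: QuadraticModel) -> dict[str, Any]:
    return {
        "terms": list(model.terms),
        "coef": model.coef.tolist(),
        "stderr": model.stderr.tolist(),
        "t": model.tvalues.tolist(),
        "p": model.pvalues.tolist(),
        "r_squared": model.r_squared,
        "df_resid": model.df_resid,
        "n_runs": model.n_runs,
    }


def stationary_to_dict(sp: StationaryPoint) -> dict[str, Any]:
    return {
        "free_factors": list(sp.free_factors),
        "coded": None if sp.coded is None else sp.coded.tolist(),
        "physical": sp.physical,
        "predicted": sp.predicted,
        "nature": sp.nature,
        "eigenvalues": sp.eigenvalues.tolist(),
        "fixed": sp.fixed,
        "message": sp.message,
    }


def incorporation_to_dict(res: IncorporationResult) -> dict[str, Any]:
    return {
        "plfa": list(res.names),
        "excess_13c_mg_per_kg": res.excess.tolist(),
        "pct_of_added_13c": res.pct_of_added.tolist(),
        "pct_distribution": _jsonable(res.pct_distribution),
        "negative_excess": res.negative_flags.tolist(),
        "total_excess_mg_per_kg": res.total_excess,
        "total_pct_of_added": res.total_pct_of_added,
        "warnings": list(res.warnings),
    }


def _sig4(x: float) -> str:
    return f"{x:.4g}"


def _render_text(report: AnalysisReport) -> str:
    lines = ["# degratrace analysis report", ""]
    if report.rsm:
        lines.append("## Response-surface fit")
        for key in ("full", "pruned"):
            sec = report.rsm.get(key)
            if not sec:
                continue
            lines.append(f"[{key} model]  R^2 = {_sig4(sec['r_squared'])}")
            for t, c, p in zip(sec["terms"], sec["coef"], sec["p"]):
                lines.append(f"  {t:8s} coef = {_sig4(c):>10s}   p = {_sig4(p)}")
        sp = report.rsm.get("stationary_point")
        if sp:
            lines.append(
                f"stationary point: nature={sp['nature']}, coded={sp['coded']}, "
                f"predicted={_sig4(sp['predicted']) if sp['predicted'] is not None else 'n/a'}"
            )
        lines.append("")
    if report.sip:
        lines.append("## 13C-PLFA incorporation")
        for n, pct in zip(report.sip["plfa"], report.sip["pct_of_added_13c"]):
            lines.append(f"  {n:20s} {_sig4(pct)} % of added 13C")
        lines.append(f"  total: {_sig4(report.sip['total_pct_of_added'])} % of added 13C")
        lines.append("")
    if report.degradation:
        lines.append("## Degradation bookkeeping")
        for k, v in report.degradation.items():
            lines.append(f"  {k}: {v if isinstance(v, str) else _sig4(v)}")
        lines.append("")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report atomically (no partial files on error)."""
    path = Path(path)
    if format == "json":
        payload = json.dumps(_jsonable(dataclasses.asdict(report)), indent=2, sort_keys=True)
    elif format == "text":
        payload = _render_text(report)
    else:
        raise ValueError(f"format must be 'json' or 'text', got {format!r}")
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
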