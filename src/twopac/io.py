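"""CSV and JSON file formats for survival data and fit reports.

All tables are comma-separated, UTF-8, dot-decimal, with a header row;
every time column is in days.  Fit reports are JSON with parameters stored
as decimal strings so values round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, SurvivalCurve

__all__ = [
    "FitReport",
    "read_survival_table",
    "read_smurf_counts",
    "write_fit_report",
    "read_fit_report",
    "write_lifespans",
    "read_lifespans",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FitReport:
    """Serializable wrapper around a :class:`~twopac.fitting.FitResult`."""

    result: FitResult
    input_name: str = ""
    input_rows: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        r = self.result
        return {
            "schema_version": SCHEMA_VERSION,
            "tool": "twopac",
            "tool_version": __version__,
            "model_name": r.model_name,
            "parameters": {k: repr(float(v)) for k, v in r.params.items()},
            "units": _UNITS.get(r.model_name, {}),
            "sse": repr(float(r.sse)),
            "r2": repr(float(r.r2)),
            "aic": repr(float(r.aic)),
            "n_points": r.n_points,
            "converged": bool(r.converged),
            "input": {"name": self.input_name, "rows": self.input_rows},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitReport":
        result = FitResult(
            model_name=d["model_name"],
            params={k: float(v) for k, v in d["parameters"].items()},
            sse=float(d["sse"]),
            r2=float(d["r2"]),
            aic=float(d["aic"]),
            n_points=int(d["n_points"]),
            converged=bool(d["converged"]),
        )
        return cls(result=result, input_name=d["input"]["name"],
                   input_rows=int(d["input"]["rows"]), seed=d.get("seed"))


_UNITS = {
    "2pac": {"a": "1/day", "t0": "day", "k": "1/day", "k_fixed": "1/day"},
    "gompertz": {"a0": "1/day", "g": "1/day"},
    "weibull": {"scale_a": "1/day^shape_k", "shape_k": ""},
}


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_survival_table(path, dialect: str = "fraction",
                        n0: float | None = None) -> SurvivalCurve:
    """Read a survival curve from CSV.

    ``dialect="fraction"`` expects columns ``time, alive_fraction``;
    ``dialect="count"`` expects ``time, n_alive`` normalised by ``n0`` (or,
    if omitted, by the first row's count).  Errors name the offending row
    (1-based, excluding the header).
    """
    if dialect not in ("fraction", "count"):
        raise ValueError("dialect must be 'fraction' or 'count'")
    col = "alive_fraction" if dialect == "fraction" else "n_alive"
    df = _read_csv(path, {"time", col})
    t = df["time"].to_numpy(dtype=float)
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            raise ValueError(
                f"{path}: row {i + 1}: time {t[i]} not strictly greater "
                f"than previous {t[i - 1]}"
            )
    v = df[col].to_numpy(dtype=float)
    if dialect == "count":
        if np.any(v < 0):
            row = int(np.nonzero(v < 0)[0][0]) + 1
            raise ValueError(f"{path}: row {row}: negative count")
        denom = float(n0) if n0 is not None else float(v[0])
        if denom <= 0:
            raise ValueError(f"{path}: n0 must be positive")
        v = v / denom
    bad = (v < 0) | (v > 1)
    if np.any(bad):
        row = int(np.nonzero(bad)[0][0]) + 1
        raise ValueError(
            f"{path}: row {row}: alive fraction {v[row - 1]} outside [0, 1]"
        )
    rising = np.diff(v) > 1e-9
    if np.any(rising):
        row = int(np.nonzero(rising)[0][0]) + 2
        raise ValueError(f"{path}: row {row}: alive fraction increases")
    return SurvivalCurve(times=t, alive_fraction=v)


def read_smurf_counts(path) -> pd.DataFrame:
    """Read a Smurf-assay table (``time, n_smurf, n_nonsmurf``) from CSV."""
    df = _read_csv(path, {"time", "n_smurf", "n_nonsmurf"})
    for col in ("n_smurf", "n_nonsmurf"):
        vals = df[col].to_numpy()
        if np.any(vals < 0):
            row = int(np.nonzero(vals < 0)[0][0]) + 1
            raise ValueError(f"{path}: row {row}: negative {col}")
        if not np.allclose(vals, np.round(vals)):
            row = int(np.nonzero(~np.isclose(vals, np.round(vals)))[0][0]) + 1
            raise ValueError(f"{path}: row {row}: non-integer {col}")
    out = df[["time", "n_smurf", "n_nonsmurf"]].copy()
    out["n_smurf"] = out["n_smurf"].astype(np.int64)
    out["n_nonsmurf"] = out["n_nonsmurf"].astype(np.int64)
    return out.sort_values("time", kind="stable").reset_index(drop=True)


def write_fit_report(result: FitResult, path, input_name: str = "",
                     input_rows: int = 0, seed: int | None = None) -> None:
    """Write a fit result as a versioned JSON report."""
    if not np.isfinite(result.sse) or not np.isfinite(result.r2):
        raise ValueError("cannot serialize a non-finite fit result")
    report = FitReport(result=result, input_name=input_name,
                       input_rows=input_rows, seed=seed)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_report(path) -> FitReport:
    """Read back a JSON fit report; numeric values round-trip exactly."""
    with open(path, "r", encoding="utf-8") as fh:
        return FitReport.from_dict(json.load(fh))


def write_lifespans(records: pd.DataFrame, path) -> None:
    """Write a lifespan table (``individual_id, smurf_time, death_time``)."""
    records.to_csv(path, index=False)


def read_lifespans(path) -> pd.DataFrame:
    """Read a lifespan table written by :func:`write_lifespans`."""
    df = _read_csv(path, {"individual_id", "smurf_time", "death_time"})
    bad = ~(
        (df["smurf_time"] >= 0) & (df["smurf_time"] < df["death_time"])
    ).to_numpy()
    if np.any(bad):
        row = int(np.nonzero(bad)[0][0]) + 1
        raise ValueError(
            f"{path}: row {row}: need 0 <= smurf_time < death_time"
        )
    return df
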