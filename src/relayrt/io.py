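"""Delimited-text readers/writers for trial tables, quantiles, curves, fits.

All formats are small comma- or tab-separated tables (autodetected on read);
times are milliseconds end-to-end and probabilities live in [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .ig import DistCurve, IGParams
from .metrics import QuantileSet

__all__ = [
    "read_trials",
    "write_trials",
    "read_quantiles",
    "write_quantiles",
    "read_curve",
    "write_curve",
    "read_ig_params",
    "write_ig_params",
    "read_fit",
    "write_fit",
]

TRIAL_COLUMNS = ["participant", "block", "condition", "soa_ms", "rt_ms"]


def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    return df


def _require_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} at line {line}")
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
    return vals.to_numpy(dtype=float)


def read_trials(path) -> pd.DataFrame:
    """Read a tidy trial table; rejects non-numeric or non-positive RTs."""
    df = _read_table(path, TRIAL_COLUMNS)
    rt = _require_numeric(df, "rt_ms", path)
    _require_numeric(df, "soa_ms", path)
    if np.any(rt <= 0):
        line = int(np.argmax(rt <= 0)) + 2
        raise ValueError(f"{path}: non-positive RT at line {line}")
    return df[TRIAL_COLUMNS].copy()


def write_trials(path, df: pd.DataFrame) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_quantiles(path) -> QuantileSet:
    """Read a (prob, rt_ms) quantile table."""
    df = _read_table(path, ["prob", "rt_ms"])
    probs = _require_numeric(df, "prob", path)
    rts = _require_numeric(df, "rt_ms", path)
    return QuantileSet(probs, rts)


def write_quantiles(path, q: QuantileSet) -> None:
    pd.DataFrame({"prob": q.probs, "rt_ms": q.rts}).to_csv(path, index=False)


def read_curve(path) -> DistCurve:
    df = _read_table(path, ["t_ms", "cdf"])
    return DistCurve(_require_numeric(df, "t_ms", path), _require_numeric(df, "cdf", path))


def write_curve(path, curve: DistCurve) -> None:
    cols = {"t_ms": curve.t, "cdf": curve.cdf}
    if curve.pdf is not None:
        cols["pdf"] = curve.pdf
    pd.DataFrame(cols).to_csv(path, index=False)


def read_ig_params(path) -> dict[str, IGParams]:
    """Read a (label, mu_ms, lambda_ms) parameter table into a dict."""
    df = _read_table(path, ["label", "mu_ms", "lambda_ms"])
    mu = _require_numeric(df, "mu_ms", path)
    lam = _require_numeric(df, "lambda_ms", path)
    return {str(l): IGParams(m, la) for l, m, la in zip(df["label"], mu, lam)}


def write_ig_params(path, params: dict[str, IGParams]) -> None:
    pd.DataFrame(
        {"label": list(params), "mu_ms": [p.mu for p in params.values()], "lambda_ms": [p.lam for p in params.values()]}
    ).to_csv(path, index=False)


def _params_to_jsonable(params):
    if isinstance(params, IGParams):
        return {"mu": params.mu, "lam": params.lam}
    return params


def write_fit(path, fit: FitResult) -> None:
    """Serialise a fit result as structured text (JSON)."""
    payload = {
        "params": _params_to_jsonable(fit.params),
        "objective": fit.objective,
        "objective_name": fit.objective_name,
        "converged": fit.converged,
        "evaluations": fit.evaluations,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    params = d["params"]
    if isinstance(params, dict) and set(params) == {"mu", "lam"}:
        params = IGParams(**params)
    return FitResult(params, d["objective"], d["converged"], d["evaluations"], d.get("objective_name", ""))
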