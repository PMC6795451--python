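"""File I/O: CSV time-series dialects, parameter JSON, run reports.

Dialects are fixed: comma-separated, UTF-8, header required, times in days
as floats, percents on the 0-100 scale.  All rates in parameter JSON are
fractions per day.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from .pk import BiexponentialParams, PKFit
from .ptm import FirstOrderPTMParams, PTMFit
from .reference import GOOD_FIT_R2

logger = logging.getLogger("pqakin")

_SCHEMAS = {
    "pk": ["subject_id", "time_days", "conc_ug_per_ml"],
    "ptm": ["subject_id", "site_id", "time_days", "ptm_percent"],
    "peak_areas": ["sample_id", "site_id", "time_days", "modified_area", "native_area"],
}
_SORT_KEYS = {
    "pk": ["subject_id", "time_days"],
    "ptm": ["subject_id", "site_id", "time_days"],
    "peak_areas": ["sample_id", "site_id", "time_days"],
}


def read_timeseries_csv(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the standard CSV dialects.

    kind is "pk", "ptm" or "peak_areas".  Missing columns and non-numeric
    cells are fatal with the offending column/row named; unsorted times are
    accepted, sorted, and logged; an empty file is an explicit error.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"kind must be one of {sorted(_SCHEMAS)}, got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no records")
    numeric = [c for c in required if c not in ("subject_id", "site_id", "sample_id")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row(s) "
                f"{[int(i) + 2 for i in bad[:5]]} (1-based, incl. header)")
        df[col] = converted
    keys = _SORT_KEYS[kind]
    if not df[keys].equals(df[keys].sort_values(keys, kind="stable").reset_index(drop=True)):
        logger.warning("%s: rows not sorted by %s; sorting", path, keys)
        df = df.sort_values(keys, kind="stable").reset_index(drop=True)
    return df[list(df.columns)]


def read_pk_params_json(path) -> BiexponentialParams:
    """Load {A, B, alpha, beta} from a JSON parameter file."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return BiexponentialParams(A=d["A"], B=d["B"], alpha=d["alpha"], beta=d["beta"])


def write_pk_params_json(params: BiexponentialParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"A": params.A, "B": params.B, "alpha": params.alpha,
                   "beta": params.beta}, fh, indent=2)
        fh.write("\n")


def read_ptm_params_json(path) -> FirstOrderPTMParams:
    """Load {p0, k[, site]} (fractions and fraction/day) from JSON.

    Set "percent_per_day": true in the file if k is recorded on the percent
    scale; it is divided by 100 on read.
    """
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    scale = 0.01 if d.get("percent_per_day") else 1.0
    return FirstOrderPTMParams(p0=d["p0"] * scale, k=d["k"] * scale,
                               site=d.get("site", ""))


def write_ptm_params_json(params: FirstOrderPTMParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"p0": params.p0, "k": params.k, "site": params.site}, fh, indent=2)
        fh.write("\n")


def fit_to_dict(fit: PKFit | PTMFit) -> dict:
    """JSON-ready summary of a fit, flagging R^2 below the good-fit bar."""
    if isinstance(fit, PKFit):
        params = {"A": fit.params.A, "B": fit.params.B,
                  "alpha": fit.params.alpha, "beta": fit.params.beta}
    else:
        params = {"p0": fit.params.p0, "k": fit.params.k, "site": fit.params.site}
    d = {
        "params": params,
        "standard_errors": dict(fit.se),
        "r_squared": fit.r_squared,
        "converged": fit.converged,
        "good_fit": bool(fit.r_squared >= GOOD_FIT_R2) if fit.r_squared == fit.r_squared else False,
    }
    if not d["good_fit"]:
        d["warning"] = f"poor fit: R^2 below {GOOD_FIT_R2}"
    return d


def write_report(results: dict, path, config: dict | None = None) -> None:
    """Write a machine-readable JSON report (full precision) plus a short
    human-readable .txt summary next to it, echoing the run configuration."""
    from . import __version__

    path = Path(path)
    payload = {"tool": "pqakin", "version": __version__,
               "config": config or {}, "results": results}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")
    lines = [f"pqakin {__version__}", ""]
    if config:
        lines.append("configuration:")
        lines += [f"  {k} = {v}" for k, v in config.items()]
        lines.append("")
    lines.append("results:")

    def render(d, indent=1):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append("  " * indent + f"{k}:")
                render(v, indent + 1)
            elif isinstance(v, float):
                lines.append("  " * indent + f"{k} = {v:.6g}")
            else:
                lines.append("  " * indent + f"{k} = {v}")

    render(results)
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
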