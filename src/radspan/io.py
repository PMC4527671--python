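"""File formats and report writers.

Three CSV dialects (comma-separated, '.' decimal, UTF-8, header row):

* lifespan: subject_id, sex, dose_cgy, group, replicate, age_days, event
* long-format Ct: gene, sample_id, group, bio_rep, tech_rep, ct
* efficiencies: gene, efficiency

Readers validate strictly (missing required columns abort; unknown columns
warn; invariant violations are reported with 1-based data row numbers).
Report writers emit a human-readable TSV with display rounding and a JSON
twin carrying every number at full precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_lifespan_csv",
    "write_lifespan_csv",
    "read_ct_csv",
    "write_ct_csv",
    "read_efficiencies_csv",
    "write_efficiencies_csv",
    "write_json_report",
    "summary_table",
    "write_summary_tsv",
]

LIFESPAN_COLUMNS = ["subject_id", "sex", "dose_cgy", "group", "replicate", "age_days", "event"]
CT_COLUMNS = ["gene", "sample_id", "group", "bio_rep", "tech_rep", "ct"]
EFF_COLUMNS = ["gene", "efficiency"]


class SchemaError(ValueError):
    """An input file violates its dialect's schema or invariants."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=3)


def _row_errors(mask: pd.Series, message: str, path) -> None:
    if mask.any():
        rows = (mask[mask].index + 1).tolist()[:20]  # 1-based data rows
        raise SchemaError(f"{path}: {message} at data row(s) {rows}")


def read_lifespan_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, LIFESPAN_COLUMNS, path)
    df = df[LIFESPAN_COLUMNS].copy()
    df["dose_cgy"] = pd.to_numeric(df["dose_cgy"], errors="coerce")
    df["age_days"] = pd.to_numeric(df["age_days"], errors="coerce")
    _row_errors(df["age_days"].isna(), "non-numeric age_days", path)
    _row_errors(df["age_days"] <= 0, "age_days must be > 0", path)
    _row_errors(df["dose_cgy"].isna() | (df["dose_cgy"] < 0), "dose_cgy must be >= 0", path)
    df["event"] = df["event"].map(
        {True: True, False: False, 1: True, 0: False, "True": True, "False": False,
         "true": True, "false": False, "1": True, "0": False})
    _row_errors(df["event"].isna(), "event flag must be boolean", path)
    df["event"] = df["event"].astype(bool)
    return df


def write_lifespan_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[LIFESPAN_COLUMNS].to_csv(path, index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CT_COLUMNS, path)
    df = df[CT_COLUMNS].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    _row_errors(df["ct"].isna(), "non-numeric Ct", path)
    _row_errors(df["ct"] <= 0, "Ct must be > 0", path)
    return df


def write_ct_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[CT_COLUMNS].to_csv(path, index=False)


def read_efficiencies_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    _check_columns(df, EFF_COLUMNS, path)
    eff = pd.to_numeric(df["efficiency"], errors="coerce")
    _row_errors(eff.isna() | (eff <= 1.0) | (eff > 2.2),
                "efficiency must be in (1, 2.2]", path)
    return pd.Series(eff.to_numpy(), index=df["gene"].to_numpy(), name="efficiency")


def write_efficiencies_csv(eff: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": eff.index, "efficiency": eff.to_numpy()}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(payload: Any, path: str | Path) -> None:
    """Full-precision JSON report (deterministic key order)."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _fmt(value, spec: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    return format(value, spec)


def summary_table(summaries) -> pd.DataFrame:
    """Table-1-layout frame with display rounding.

    Columns: Sex, Dose, M, dM%, 90%, d90%, MRDT, dMRDT%, alpha, R0, R2, N.
    Medians and 90%-mortality ages print as whole days, MRDT to 2 dp,
    percents to 1 dp, alpha to 3 dp.
    """
    rows = []
    for s in summaries:
        rows.append({
            "Sex": s.sex,
            "Dose_cGy": f"{s.dose_cgy:g}",
            "M": _fmt(s.median, ".0f"),
            "dM_pct": _fmt(s.delta_median_pct, ".1f"),
            "90pct": _fmt(s.age90, ".0f"),
            "d90_pct": _fmt(s.delta_age90_pct, ".1f"),
            "MRDT": _fmt(s.mrdt_days, ".2f"),
            "dMRDT_pct": _fmt(s.delta_mrdt_pct, ".1f"),
            "alpha": _fmt(s.alpha, ".3f"),
            "R0": _fmt(s.r0, ".2e"),
            "R2": _fmt(s.r_squared, ".3f"),
            "N": s.n,
        })
    return pd.DataFrame(rows)


def write_summary_tsv(summaries, path: str | Path) -> None:
    summary_table(summaries).to_csv(path, sep="\t", index=False)
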