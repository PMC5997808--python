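"""CSV/JSON interchange for trials, power series, MMP tables and reports.

All files are UTF-8 CSV with a header row and decimal points.  Readers
validate schema and values with line-numbered messages; unknown columns
are warned about, never fatal.  Nothing here mutates input files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pdcurve import AOTTrace, CPFit, PerformanceTrial, Protocol
from .passport import MMPTable, PassportYearReport
from .wbal import PowerTimeSeries, WbalTrace

logger = logging.getLogger("critpower")

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _require_positive(df: pd.DataFrame, col: str, path: PathLike):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() | (vals <= 0)]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise ValidationError(
            f"{path}: line {bad[0] + 2}: column {col!r} must be a positive number, "
            f"got {df.loc[bad[0], col]!r}"
        )
    return vals.astype(float)


def _warn_unknown(df: pd.DataFrame, known: Sequence[str], path: PathLike):
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)


def read_trials_csv(path: PathLike) -> list:
    """Performance trials from columns duration_s, power_w[, work_j, protocol, year]."""
    df = _read_csv(path, ["duration_s", "power_w"])
    _warn_unknown(df, ["duration_s", "power_w", "work_j", "protocol", "year", "date"], path)
    durations = _require_positive(df, "duration_s", path)
    powers = _require_positive(df, "power_w", path)
    trials = []
    for i in df.index:
        work = None
        if "work_j" in df.columns and pd.notna(df.loc[i, "work_j"]):
            work = float(df.loc[i, "work_j"])
        proto = Protocol.CONSTANT_DURATION
        if "protocol" in df.columns and pd.notna(df.loc[i, "protocol"]):
            try:
                proto = Protocol(str(df.loc[i, "protocol"]).strip().lower())
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {i + 2}: unknown protocol {df.loc[i, 'protocol']!r}"
                ) from exc
        year = None
        if "year" in df.columns and pd.notna(df.loc[i, "year"]):
            year = int(df.loc[i, "year"])
        try:
            trials.append(
                PerformanceTrial(
                    duration_s=float(durations[i]),
                    power_w=float(powers[i]),
                    work_j=work,
                    protocol=proto,
                    year=year,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return trials


def read_power_series_csv(path: PathLike) -> PowerTimeSeries:
    """Uniformly sampled power series from columns time_s, power_w."""
    df = _read_csv(path, ["time_s", "power_w"])
    _warn_unknown(df, ["time_s", "power_w"], path)
    try:
        return PowerTimeSeries(
            time_s=df["time_s"].to_numpy(float), power_w=df["power_w"].to_numpy(float)
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_aot_trace_csv(path: PathLike) -> AOTTrace:
    """3-min all-out trace from columns time_s, power_w (uniform step <= 1 s)."""
    df = _read_csv(path, ["time_s", "power_w"])
    _warn_unknown(df, ["time_s", "power_w"], path)
    try:
        return AOTTrace(
            time_s=df["time_s"].to_numpy(float), power_w=df["power_w"].to_numpy(float)
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_mmp_csv(path: PathLike) -> MMPTable:
    """MMP table from columns year, duration_s, power_w[, provenance]."""
    df = _read_csv(path, ["year", "duration_s", "power_w"])
    _warn_unknown(df, list(MMPTable.COLUMNS), path)
    _require_positive(df, "duration_s", path)
    _require_positive(df, "power_w", path)
    try:
        return MMPTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_mmp_csv(table: MMPTable, path: PathLike):
    table.df.to_csv(path, index=False)


def write_trials_csv(trials: Sequence[PerformanceTrial], path: PathLike):
    pd.DataFrame(
        {
            "duration_s": [t.duration_s for t in trials],
            "power_w": [t.power_w for t in trials],
            "work_j": [t.work for t in trials],
            "protocol": [t.protocol.value for t in trials],
            "year": [t.year for t in trials],
        }
    ).to_csv(path, index=False)


def write_wbal_csv(trace: WbalTrace, path: PathLike):
    pd.DataFrame(
        {"time_s": trace.time_s, "power_w": trace.power_w, "wbal_j": trace.wbal_j}
    ).to_csv(path, index=False)


def fit_to_dict(fit: CPFit) -> dict:
    cov = fit.cov
    return {
        "cp_w": fit.cp,
        "w_prime_j": fit.w_prime,
        "se_cp": _jsonable(fit.se_cp),
        "se_w_prime": _jsonable(fit.se_w_prime),
        "cov": [[_jsonable(cov[i, j]) for j in range(2)] for i in range(2)],
        "n": fit.n,
        "form": fit.form.value,
        "r_squared": _jsonable(fit.r_squared),
        "duration_range_s": list(fit.duration_range_s),
        "residuals": [_jsonable(r) for r in np.asarray(fit.residuals)],
    }


def _jsonable(x):
    x = float(x)
    return None if not np.isfinite(x) else x


def write_fit_json(fit: CPFit, path: PathLike):
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n", encoding="utf-8")


def report_to_dict(report: PassportYearReport) -> dict:
    return {
        "test_year": report.test_year,
        "baseline_years": report.baseline_years,
        "n_baseline_points": report.n_baseline_points,
        "level": report.level,
        "performances": [
            {
                "duration_s": float(a.duration_s),
                "observed_w": float(a.observed_w),
                "predicted_w": float(a.predicted_w),
                "pi_low_w": float(a.pi_low_w),
                "pi_high_w": float(a.pi_high_w),
                "flagged": bool(a.flagged),
            }
            for a in report.performances
        ],
        "cp": _param_dict(report.cp),
        "w_prime": _param_dict(report.w_prime),
    }


def _param_dict(p) -> dict:
    return {
        "baseline_estimate": float(p.baseline_estimate),
        "ci_low": float(p.ci_low),
        "ci_high": float(p.ci_high),
        "test_estimate": None if p.test_estimate is None else float(p.test_estimate),
        "flagged": None if p.flagged is None else bool(p.flagged),
    }


def write_passport_json(reports: Sequence[PassportYearReport], path: PathLike):
    payload = [report_to_dict(r) for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
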