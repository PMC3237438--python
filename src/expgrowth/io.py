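"""Tabular I/O and fit reports.

All data files are comma-separated UTF-8 text with a header and "." decimal
point; time is a decimal week number (no date parsing).  Reports carry the
full-precision numbers first and a rounded display block mirroring the
published precision (Q to 3 d.p., uptake to whole kg/ha).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import YieldFit
from .phase import PhaseParams
from .series import FieldSeries

__all__ = ["read_field_series", "write_field_series", "write_report", "read_report"]

log = logging.getLogger(__name__)

#: Allowed mismatch between a stated concentration column and uptake/Y,
#: in printed units (g/kg): published uptakes are rounded to whole kg.
CONCENTRATION_TOLERANCE = 0.5


def read_field_series(path: str | Path) -> FieldSeries:
    """Parse a sampling-series CSV into a FieldSeries.

    Requires ``t`` and ``Y`` columns; element columns ``<el>_u`` (kg/ha) and
    optionally ``<el>_c`` (g/kg) are picked up by suffix.  Stated
    concentrations are validated against uptake/Y; disagreement beyond
    CONCENTRATION_TOLERANCE is a warning (rounded source data), not an
    error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file (a header row is required)") from exc
    for col in ("t", "Y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    series = FieldSeries(data=df, provenance="user")
    for el in series.elements:
        ccol = f"{el}_c"
        if ccol not in df.columns:
            continue
        y = df["Y"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            implied = np.where(y > 0, df[f"{el}_u"].to_numpy(dtype=float) / y, np.nan)
        dev = np.abs(implied - df[ccol].to_numpy(dtype=float))
        for i in np.flatnonzero(dev > CONCENTRATION_TOLERANCE):
            log.warning(
                "%s: %s at t=%s is %.3g but uptake/Y gives %.3g (beyond +/-%.1f)",
                path, ccol, df["t"].iloc[i], df[ccol].iloc[i], implied[i], CONCENTRATION_TOLERANCE,
            )
    return series


def write_field_series(series: FieldSeries, path: str | Path) -> None:
    """Write a series as CSV (header t,Y,<el>_u,<el>_c...)."""
    series.data.to_csv(path, index=False)


def _display_block(results: list) -> dict:
    disp: dict[str, dict] = {}
    for r in results:
        if isinstance(r, YieldFit):
            disp["yield_fit"] = {"A": round(r.A, 2), "b": round(r.b, 2), "r2": round(r.r2, 3)}
        elif isinstance(r, PhaseParams):
            disp[f"phase_{r.element}"] = {
                "N_um_kg_ha": round(r.N_um),
                "K_y_Mg_ha": round(r.K_y, 1),
                "r2": round(r.r2_linear, 3),
            }
    return disp


def write_report(results, path: str | Path) -> None:
    """Write fit results (YieldFit / PhaseParams, singly or in a list) as JSON.

    Field order is deterministic; full precision is kept under ``fits`` and
    a rounded ``display`` block mirrors the published precision.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    payload: dict = {"fits": [], "display": _display_block(list(results))}
    for r in results:
        entry = asdict(r)
        entry["kind"] = type(r).__name__
        payload["fits"].append(entry)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> list:
    """Read a report back into YieldFit / PhaseParams objects (exact round-trip)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for entry in payload["fits"]:
        kind = entry.pop("kind")
        cls = {"YieldFit": YieldFit, "PhaseParams": PhaseParams}[kind]
        out.append(cls(**entry))
    return out
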