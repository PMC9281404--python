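"""Readers and writers for on-disk formats.

Time series arrive either as GROMACS XVG energy output (``#`` comments,
``@`` directives, whitespace-separated data, time in the first column) or
as plain CSV with a header row.  Results serialize to JSON (lossless,
round-trippable) or CSV (one row per quantity).  Stretch curves and
lambda-legs use small documented CSV schemas; peptide populations use
FASTA.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alchemy import CycleClosureReport, LambdaLeg, TIResult
from .mechanics import SensingResult, StretchCurve
from .tension import PressureTrace, TensionEstimate

log = logging.getLogger("chaoscalc")

__all__ = [
    "TimeSeriesTable",
    "read_xvg",
    "read_csv_table",
    "read_pressure_trace",
    "read_curve_csv",
    "write_curve_csv",
    "read_lambda_leg_csv",
    "write_lambda_leg_csv",
    "write_report",
    "read_report",
    "read_population_fasta",
    "write_population_fasta",
]


@dataclass
class TimeSeriesTable:
    """Ordered time column plus named equal-length value columns."""

    time: np.ndarray
    columns: dict[str, np.ndarray]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size < 1:
            raise ValueError("table needs at least one row")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if col.size != self.time.size:
                raise ValueError(f"column {name!r} length mismatch")
            self.columns[name] = col


_LEGEND_RE = re.compile(r'^@\s*s(\d+)\s+legend\s+"(.*)"')


def read_xvg(path: str | Path) -> TimeSeriesTable:
    """Parse a GROMACS XVG text file into a :class:`TimeSeriesTable`.

    ``#`` lines are comments, ``@`` lines directives; ``s<i> legend``
    directives name the value columns, which otherwise become
    ``col1``, ``col2``, ...  The first data column is time (ps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    legends: dict[int, str] = {}
    metadata: dict[str, str] = {}
    rows: list[list[float]] = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                m = _LEGEND_RE.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                else:
                    parts = line[1:].strip().split(None, 1)
                    if len(parts) == 2:
                        metadata[parts[0]] = parts[1].strip('"')
                continue
            tokens = line.split()
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token in data line") from exc
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise ValueError(f"{path}:{lineno}: ragged data line ({len(values)} fields, expected {n_cols})")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows)
    names = [legends.get(i, f"col{i + 1}") for i in range(data.shape[1] - 1)]
    columns = {name: data[:, i + 1] for i, name in enumerate(names)}
    return TimeSeriesTable(time=data[:, 0], columns=columns, metadata=metadata)


def read_csv_table(path: str | Path, time_column: str | None = None) -> TimeSeriesTable:
    """Read a CSV with header row; the time column defaults to the first."""
    df = pd.read_csv(path)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")
    if time_column is None:
        time_column = df.columns[0]
    if time_column not in df.columns:
        raise KeyError(f"{path}: no column {time_column!r}")
    time = df[time_column].to_numpy(dtype=float)
    columns = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != time_column
    }
    return TimeSeriesTable(time=time, columns=columns)


#: GROMACS energy-file column names tried first during auto-detection.
DEFAULT_COLUMN_MAP = {
    "Pxx": "Pres-XX",
    "Pyy": "Pres-YY",
    "Pzz": "Pres-ZZ",
    "Lz": "Box-Z",
}

SURFTEN_COLUMN = "#Surf*SurfTen"


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def _find_column(table: TimeSeriesTable, wanted: str) -> str | None:
    if wanted in table.columns:
        return wanted
    target = _normalize(wanted)
    for name in table.columns:
        if _normalize(name) == target:
            log.info("fuzzy-matched column %r to requested %r", name, wanted)
            return name
    return None


def read_pressure_trace(
    table: TimeSeriesTable,
    column_map: dict[str, str] | None = None,
    area: float | None = None,
    area_column: str | None = None,
    lz: float | None = None,
    label: str = "",
) -> PressureTrace:
    """Map a time-series table onto a :class:`PressureTrace`.

    ``column_map`` maps canonical names (``Pxx``, ``Pyy``, ``Pzz``, ``Lz``)
    to the table's column names; unmapped names fall back to the GROMACS
    energy names and then to a case-insensitive fuzzy match.  The constant
    box area comes from ``area`` (nm^2) or from ``area_column``; ``lz``
    supplies a constant box height when no height column exists.
    """
    if area is not None and area_column is not None:
        raise ValueError("supply either a constant area or an area column, not both")
    if area is None and area_column is None:
        raise ValueError("a box area is required (constant or column)")
    requested = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(requested)
        if unknown:
            raise KeyError(f"unknown canonical names in column_map: {sorted(unknown)}")
        requested.update(column_map)

    resolved: dict[str, np.ndarray] = {}
    for canonical, wanted in requested.items():
        found = _find_column(table, wanted)
        if found is None:
            if canonical == "Lz" and lz is not None:
                resolved["Lz"] = np.broadcast_to(float(lz), table.time.shape)
                continue
            raise KeyError(
                f"column {wanted!r} (for {canonical}) not found; "
                f"available: {sorted(table.columns)}"
            )
        resolved[canonical] = table.columns[found]

    if area_column is not None:
        found = _find_column(table, area_column)
        if found is None:
            raise KeyError(f"area column {area_column!r} not found")
        area_values = table.columns[found]
        if np.ptp(area_values) > 1e-9:
            raise ValueError("area column is not constant; constant-area runs expected")
        area = float(area_values[0])

    surften_name = _find_column(table, SURFTEN_COLUMN)
    surften = table.columns[surften_name] if surften_name else None

    return PressureTrace(
        time=table.time,
        pxx=resolved["Pxx"],
        pyy=resolved["Pyy"],
        pzz=resolved["Pzz"],
        lz=resolved["Lz"],
        area=float(area),
        label=label,
        surften=surften,
    )


# ---------------------------------------------------------------------------
# stretch curves (CSV schema: area_nm2, sigma_mNm, sem_mNm)

def read_curve_csv(path: str | Path, label: str = "") -> StretchCurve:
    df = pd.read_csv(path)
    for col in ("area_nm2", "sigma_mNm"):
        if col not in df.columns:
            raise KeyError(f"{path}: curve CSV needs column {col!r}")
    sems = df["sem_mNm"].to_numpy(dtype=float) if "sem_mNm" in df.columns else None
    return StretchCurve.from_arrays(
        areas=df["area_nm2"].to_numpy(dtype=float),
        sigmas=df["sigma_mNm"].to_numpy(dtype=float),
        sems=sems,
        label=label,
    )


def write_curve_csv(curve: StretchCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"area_nm2": curve.areas, "sigma_mNm": curve.sigmas, "sem_mNm": curve.sems}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# lambda legs (CSV schema: lambda, dvdl_mean, dvdl_sem)

def read_lambda_leg_csv(path: str | Path, leg: str, tension_state: str) -> LambdaLeg:
    df = pd.read_csv(path)
    for col in ("lambda", "dvdl_mean"):
        if col not in df.columns:
            raise KeyError(f"{path}: lambda-leg CSV needs column {col!r}")
    sem = (
        df["dvdl_sem"].to_numpy(dtype=float)
        if "dvdl_sem" in df.columns
        else np.zeros(len(df))
    )
    return LambdaLeg(
        leg=leg,
        lambdas=df["lambda"].to_numpy(dtype=float),
        dvdl_mean=df["dvdl_mean"].to_numpy(dtype=float),
        dvdl_sem=sem,
        tension_state=tension_state,
    )


def write_lambda_leg_csv(leg: LambdaLeg, path: str | Path) -> None:
    pd.DataFrame(
        {"lambda": leg.lambdas, "dvdl_mean": leg.dvdl_mean, "dvdl_sem": leg.dvdl_sem}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result reports

_RESULT_TYPES = {
    "SensingResult": SensingResult,
    "TIResult": TIResult,
    "TensionEstimate": TensionEstimate,
}


def _csv_rows(result) -> list[tuple[str, float, float | str, str]]:
    if isinstance(result, SensingResult):
        return [
            ("ddF_sensing", result.ddF, result.ddF_err, "kJ/mol"),
            ("delta_sigma", result.delta_sigma, "", "mN/m"),
            ("chaos", result.chaos, result.chaos_err, "nm^2"),
        ]
    if isinstance(result, TIResult):
        rows = [
            (f"dF_{leg}", val, "", "kJ/mol") for leg, val in result.dF_per_leg.items()
        ]
        rows.append(("dF_total", result.dF_total, result.dF_err, "kJ/mol"))
        return rows
    if isinstance(result, TensionEstimate):
        return [("sigma", result.sigma, result.sem, "mN/m")]
    if isinstance(result, CycleClosureReport):
        return [
            ("mechanical", result.mech, "", "kJ/mol"),
            ("alchemical", result.alch, "", "kJ/mol"),
            ("difference", result.difference, result.combined_err, "kJ/mol"),
            ("p_two_tailed", result.p if result.p is not None else float("nan"), "", ""),
        ]
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize a finalized result to JSON (lossless) or CSV (tabular).

    JSON reports round trip through :func:`read_report`; CSV reports have
    one row per quantity with columns ``name,value,error,units``.
    """
    path = Path(path)
    if format == "json":
        payload = {"type": type(result).__name__, "fields": result.to_dict()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "value", "error", "units"])
            for name, value, error, unit in _csv_rows(result):
                writer.writerow([
                    name,
                    repr(float(value)),
                    "" if error == "" else repr(float(error)),
                    unit,
                ])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path):
    """Read a JSON report back into its result object."""
    payload = json.loads(Path(path).read_text())
    cls = _RESULT_TYPES.get(payload.get("type"))
    if cls is None:
        raise ValueError(f"{path}: unknown or unsupported report type {payload.get('type')!r}")
    return cls.from_dict(payload["fields"])


# ---------------------------------------------------------------------------
# FASTA populations

def read_population_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_population_fasta(sequences: Sequence[str], path: str | Path, prefix: str = "ind") -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{prefix}{i:04d}", description="")
        for i, seq in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
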