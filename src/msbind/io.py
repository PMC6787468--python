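"""Tidy-table I/O: measurement tables, library definitions, configs, reports.

Schemas
-------
``measurements.csv`` — one row per (sample, analyte) MRM readout:
    plate_id, sublibrary_id, condition, standard_conc_nM, replicate,
    analyte_id, peak_area, is_peak_area
with condition in {total, nonspecific, control_total, control_nonspecific,
standard}; ``standard_conc_nM`` is filled only on calibration-standard rows.

``library.csv`` — one row per compound:
    compound_id, name, sublibrary_id, conc_nM, rrf, true_ki_nM, koff_s
``rrf`` may be blank (compound then not concentration-estimable);
``true_ki_nM``/``koff_s`` are simulation-only ground-truth carriers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError
from .quant import ResponseFactor

MEASUREMENT_COLUMNS = [
    "plate_id",
    "sublibrary_id",
    "condition",
    "standard_conc_nM",
    "replicate",
    "analyte_id",
    "peak_area",
    "is_peak_area",
]

CONDITIONS = {"total", "nonspecific", "control_total", "control_nonspecific", "standard"}

LIBRARY_COLUMNS = ["compound_id", "name", "sublibrary_id", "conc_nM", "rrf", "true_ki_nM", "koff_s"]


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table in place; returns it for chaining."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError("measurement table is empty")
    bad = set(df["condition"].unique()) - CONDITIONS
    if bad:
        rows = df.index[df["condition"].isin(bad)].tolist()[:5]
        raise SchemaError(
            f"unknown condition values {sorted(bad)} (first rows: {rows})"
        )
    if (df["peak_area"] < 0).any():
        rows = df.index[df["peak_area"] < 0].tolist()[:5]
        raise SchemaError(f"negative peak_area at rows {rows}")
    if (df["is_peak_area"] <= 0).any():
        rows = df.index[df["is_peak_area"] <= 0].tolist()[:5]
        raise SchemaError(f"non-positive is_peak_area at rows {rows}")
    key = ["plate_id", "sublibrary_id", "condition", "standard_conc_nM", "replicate", "analyte_id"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise SchemaError(f"duplicate (sample, analyte) keys at rows {rows}")
    std = df[df["condition"] == "standard"]
    if std["standard_conc_nM"].isna().any():
        rows = std.index[std["standard_conc_nM"].isna()].tolist()[:5]
        raise SchemaError(f"standard rows without standard_conc_nM at rows {rows}")
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurements.csv table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"plate_id": str, "sublibrary_id": str, "analyte_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty measurement file") from exc
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    validate_measurements(df)
    df.to_csv(path, index=False)


def read_library(path: str | Path):
    """Read library.csv.

    Returns ``(sublibraries, rrfs, frame)`` where ``sublibraries`` is a list of
    :class:`~msbind.pipeline.Sublibrary` in file order, ``rrfs`` maps
    compound_id to :class:`~msbind.quant.ResponseFactor` for compounds with a
    recorded RRF, and ``frame`` is the raw table (ground-truth columns intact).
    """
    from .pipeline import Sublibrary  # local import: avoid cycle

    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"compound_id": str, "sublibrary_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty library file") from exc
    missing = [c for c in ("compound_id", "sublibrary_id", "conc_nM") if c not in df.columns]
    if missing:
        raise SchemaError(f"library table missing columns: {missing}")
    for col in LIBRARY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    sublibraries = []
    for sl_id, grp in df.groupby("sublibrary_id", sort=False):
        comps = list(grp["compound_id"])
        if len(set(comps)) != len(comps):
            raise SchemaError(f"sublibrary {sl_id!r} has duplicate compound ids")
        sublibraries.append(
            Sublibrary(
                sublibrary_id=str(sl_id),
                components=tuple(comps),
                component_conc={
                    str(r.compound_id): float(r.conc_nM) for r in grp.itertuples()
                },
            )
        )
    rrfs = {
        str(r.compound_id): ResponseFactor(str(r.compound_id), float(r.rrf))
        for r in df.itertuples()
        if pd.notna(r.rrf)
    }
    return sublibraries, rrfs, df


def write_library(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_config(path: str | Path):
    """Read a config.yaml mirroring AssayConfig field names."""
    import yaml

    from .pipeline import AssayConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AssayConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return AssayConfig(**raw)


def write_config(config, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def write_report(report, out_dir: str | Path) -> None:
    """Write report.json plus flat activity.csv / hits.csv into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.activity_frame().to_csv(out_dir / "activity.csv", index=False)
    report.hits_frame().to_csv(out_dir / "hits.csv", index=False)
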