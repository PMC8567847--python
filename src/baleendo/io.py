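"""Readers and writers for the package's delimited-text formats.

The canonical plate format is long form: one row per sampling position,
columns ``position_cm`` plus any of ``progesterone_ng_g``,
``d15N_permil``, ``d13C_permil``, ``qc_flags``. Wide formats are
rejected. Values round-trip at full precision.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError
from .plate import MEASUREMENT_COLUMNS, PLATE_COLUMNS, BaleenPlate, SightingEvent, WhaleRecord

_NUMERIC_COLUMNS = ("position_cm",) + MEASUREMENT_COLUMNS


def _coerce_numeric(df: pd.DataFrame, columns) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at data row {row}",
                row=row,
            )
        df[col] = coerced
    return df


def read_plate_table(path: str | Path, whale_id: str | None = None, sep: str = ",") -> BaleenPlate:
    """Read a long-format plate table into a :class:`BaleenPlate`.

    Parameters
    ----------
    path : path
        Delimited text file with a header row.
    whale_id : str, optional
        Defaults to the file stem.
    sep : str
        Field delimiter (default comma).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if len(df) == 0:
        raise FormatError(f"{path}: table has a header but no data rows")
    if "position_cm" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column position_cm")
    if not any(c in df.columns for c in ("progesterone_ng_g", "d15N_permil")):
        raise FormatError(
            f"{path}: need at least one of progesterone_ng_g / d15N_permil"
        )
    unknown = set(df.columns) - set(PLATE_COLUMNS)
    if unknown:
        raise FormatError(f"{path}: unrecognised columns {sorted(unknown)} (wide format?)")
    df = _coerce_numeric(df, _NUMERIC_COLUMNS)
    if df["position_cm"].isna().any():
        row = int(df.index[df["position_cm"].isna()][0])
        raise ParseError(f"{path}: missing position_cm at data row {row}", row=row)
    return BaleenPlate(whale_id or path.stem, df)


def write_plate_table(plate: BaleenPlate, path: str | Path, sep: str = ",") -> None:
    """Write the canonical long-format plate table (full float precision)."""
    df = plate.data.copy()
    for col in _NUMERIC_COLUMNS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep=sep, index=False)


def read_whale_table(path: str | Path, sep: str = ",") -> dict[str, WhaleRecord]:
    """Read whale metadata; returns records keyed by whale_id."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "whale_id" not in df.columns:
        raise FormatError(f"{path}: missing whale_id column")
    records = {}
    for i, row in df.iterrows():
        def _get(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) or str(v).strip() == "" else v

        try:
            rec = WhaleRecord(
                whale_id=row["whale_id"],
                sex=_get("sex") or "unknown",
                age_years=float(_get("age_years")) if _get("age_years") else None,
                date_found=dt.date.fromisoformat(_get("date_found")) if _get("date_found") else None,
                death_date=dt.date.fromisoformat(_get("death_date")) if _get("death_date") else None,
                body_length_m=float(_get("body_length_m")) if _get("body_length_m") else None,
                foetal_length_cm=float(_get("foetal_length_cm")) if _get("foetal_length_cm") else None,
                population=_get("population") or "",
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: bad whale record at data row {i}: {exc}", row=int(i)) from exc
        records[rec.whale_id] = rec
    return records


def read_sightings_table(path: str | Path, sep: str = ",") -> dict[str, list[SightingEvent]]:
    """Read sighting histories; returns lists keyed by whale_id."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("whale_id", "date", "with_calf"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    out: dict[str, list[SightingEvent]] = {}
    truthy = {"1", "true", "yes", "y"}
    for i, row in df.iterrows():
        try:
            ev = SightingEvent(
                date=dt.date.fromisoformat(row["date"]),
                with_calf=str(row["with_calf"]).strip().lower() in truthy,
            )
        except ValueError as exc:
            raise ParseError(f"{path}: bad sighting at data row {i}: {exc}", row=int(i)) from exc
        out.setdefault(row["whale_id"], []).append(ev)
    for events in out.values():
        events.sort(key=lambda e: e.date)
    return out
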