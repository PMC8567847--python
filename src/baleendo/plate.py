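"""Domain containers for baleen plates and whale metadata.

A baleen plate is read as a longitudinal record: position 0 cm is the
newest keratin at the gumline and positions increase toward the plate
tip (oldest growth). Every module in the package shares this
convention.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError

#: Columns a plate table may carry, in canonical order.
PLATE_COLUMNS = (
    "position_cm",
    "progesterone_ng_g",
    "d15N_permil",
    "d13C_permil",
    "qc_flags",
)

MEASUREMENT_COLUMNS = ("progesterone_ng_g", "d15N_permil", "d13C_permil")


@dataclass(frozen=True)
class PlateSample:
    """One homogenised subsample at a position along the plate."""

    position_cm: float
    progesterone_ng_g: float | None = None
    d15N_permil: float | None = None
    d13C_permil: float | None = None
    qc_flags: str = ""

    def __post_init__(self):
        if self.position_cm < 0:
            raise ValueError("position_cm must be >= 0")
        if all(
            getattr(self, c) is None or (isinstance(getattr(self, c), float) and np.isnan(getattr(self, c)))
            for c in MEASUREMENT_COLUMNS
        ):
            raise ValueError(f"sample at {self.position_cm} cm carries no measurement")


class BaleenPlate:
    """Ordered per-position measurements along one baleen plate.

    Parameters
    ----------
    whale_id : str
        Identifier of the whale the plate came from.
    data : pandas.DataFrame
        Long-format table with ``position_cm`` plus at least one of
        ``progesterone_ng_g`` / ``d15N_permil``. Rows are sorted by
        position; duplicate positions are rejected.
    """

    def __init__(self, whale_id: str, data: pd.DataFrame):
        if "position_cm" not in data.columns:
            raise FormatError("plate table must have a position_cm column")
        if not any(c in data.columns for c in ("progesterone_ng_g", "d15N_permil")):
            raise FormatError(
                "plate table needs at least one of progesterone_ng_g / d15N_permil"
            )
        if len(data) == 0:
            raise FormatError("plate table has no data rows")
        df = data.copy()
        for col in PLATE_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col == "qc_flags" else np.nan
        df = df[list(PLATE_COLUMNS)]
        df["qc_flags"] = df["qc_flags"].fillna("").astype(str)
        if df["position_cm"].duplicated().any():
            dups = df.loc[df["position_cm"].duplicated(), "position_cm"].tolist()
            raise FormatError(f"duplicate sampling positions: {dups}")
        df = df.sort_values("position_cm", kind="mergesort").reset_index(drop=True)
        self.whale_id = whale_id
        self.data = df

    # -- basic accessors -------------------------------------------------
    @property
    def positions_cm(self) -> np.ndarray:
        return self.data["position_cm"].to_numpy(float)

    @property
    def plate_length_cm(self) -> float:
        return float(self.data["position_cm"].iloc[-1])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def has_isotopes(self) -> bool:
        return bool(self.data["d15N_permil"].notna().any())

    def has_progesterone(self) -> bool:
        return bool(self.data["progesterone_ng_g"].notna().any())

    def series(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions and values for one measurement, NaN rows dropped."""
        sub = self.data[["position_cm", column]].dropna()
        return sub["position_cm"].to_numpy(float), sub[column].to_numpy(float)

    @property
    def samples(self) -> list[PlateSample]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                PlateSample(
                    position_cm=float(row.position_cm),
                    progesterone_ng_g=None if pd.isna(row.progesterone_ng_g) else float(row.progesterone_ng_g),
                    d15N_permil=None if pd.isna(row.d15N_permil) else float(row.d15N_permil),
                    d13C_permil=None if pd.isna(row.d13C_permil) else float(row.d13C_permil),
                    qc_flags=row.qc_flags,
                )
            )
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BaleenPlate(whale_id={self.whale_id!r}, n_samples={self.n_samples}, "
            f"length={self.plate_length_cm:g} cm)"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BaleenPlate):
            return NotImplemented
        return self.whale_id == other.whale_id and self.data.equals(other.data)


@dataclass
class WhaleRecord:
    """Necropsy and sighting-catalogue metadata for one whale."""

    whale_id: str
    sex: str = "unknown"  # {female, male, unknown}
    age_years: float | None = None
    date_found: dt.date | None = None
    death_date: dt.date | None = None
    body_length_m: float | None = None
    foetal_length_cm: float | None = None
    population: str = ""

    def __post_init__(self):
        if self.sex not in {"female", "male", "unknown"}:
            raise ValueError(f"sex must be female/male/unknown, got {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if (
            self.death_date is not None
            and self.date_found is not None
            and self.death_date > self.date_found
        ):
            raise ValueError("death_date must be on or before date_found")
        if self.foetal_length_cm is not None:
            if self.sex != "female":
                raise ValueError("foetal_length_cm only valid for females")
            if self.foetal_length_cm <= 0:
                raise ValueError("foetal_length_cm must be positive")


@dataclass(frozen=True)
class SightingEvent:
    """One photo-identification sighting of a whale."""

    date: dt.date
    with_calf: bool = False


def validate_sightings(sightings: Iterable[SightingEvent]) -> list[SightingEvent]:
    """Sort sightings and reject duplicate dates (one record per day)."""
    out = sorted(sightings, key=lambda s: s.date)
    seen: set[dt.date] = set()
    for s in out:
        if s.date in seen:
            raise ValueError(f"duplicate sighting date {s.date}")
        seen.add(s.date)
    return out
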