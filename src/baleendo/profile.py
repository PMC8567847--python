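"""Progesterone profile normalisation and reproductive-state summaries.

Concentrations are ng immunoreactive progesterone per g baleen powder.
Z-scores normalise within a plate: (value - plate mean) / plate SD with
the sample (n-1) standard deviation, so profiles from different whales
can be compared on a common scale. Elevations are expressed as percent
above a baseline; three baseline definitions are first-class:

``full_plate_mean``
    mean of every sample on the plate (the published definition),
``nonpregnant_mean``
    mean of the samples labelled not-pregnant,
``full_plate_median``
    plate median, robust when a large fraction of the plate is
    pregnancy-elevated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BaleendoError

BASELINE_METHODS = ("full_plate_mean", "nonpregnant_mean", "full_plate_median")

STATES = ("pregnant", "not_pregnant", "unknown")


def zscores(values: np.ndarray) -> np.ndarray:
    """Within-plate z-scores: (x - plate mean) / plate SD (ddof=1)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise BaleendoError("need >=2 values for z-scores")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise BaleendoError("zero standard deviation: z-scores undefined")
    return (x - float(np.mean(x))) / sd


def baseline(
    values: np.ndarray,
    method: str = "full_plate_mean",
    labels: np.ndarray | None = None,
) -> float:
    """Scalar baseline concentration for elevation calculations."""
    x = np.asarray(values, float)
    if method not in BASELINE_METHODS:
        raise BaleendoError(f"unknown baseline method {method!r}")
    if method == "full_plate_mean":
        return float(np.mean(x))
    if method == "full_plate_median":
        return float(np.median(x))
    if labels is None:
        raise BaleendoError("nonpregnant_mean baseline needs state labels")
    mask = np.asarray(labels) == "not_pregnant"
    if not mask.any():
        raise BaleendoError("no samples labelled not_pregnant")
    return float(np.mean(x[mask]))


def percent_above(value, base: float):
    """Elevation of ``value`` over ``base``, in percent of the baseline."""
    if base <= 0:
        raise BaleendoError("baseline must be strictly positive")
    return 100.0 * (np.asarray(value, float) - base) / base


@dataclass
class StateMoments:
    mean: float
    sd: float
    n: int


@dataclass
class ProfileSummary:
    """Per-state moments plus whole-plate extremes, one plate."""

    whale_id: str
    by_state: dict[str, StateMoments]
    plate_min: float
    plate_max: float
    plate_median: float
    z_min: float
    z_max: float

    def to_frame(self) -> pd.DataFrame:
        """Summary table with rows pregnant / not pregnant / full plate."""
        rows = []
        for state in ("pregnant", "not_pregnant", "full_plate"):
            m = self.by_state.get(state)
            rows.append(
                {
                    "whale_id": self.whale_id,
                    "state": state,
                    "mean_ng_g": np.nan if m is None else m.mean,
                    "sd_ng_g": np.nan if m is None else m.sd,
                    "n": 0 if m is None else m.n,
                }
            )
        df = pd.DataFrame(rows)
        df.loc[df["state"] == "full_plate", "median_ng_g"] = self.plate_median
        df.loc[df["state"] == "full_plate", "min_ng_g"] = self.plate_min
        df.loc[df["state"] == "full_plate", "max_ng_g"] = self.plate_max
        df.loc[df["state"] == "full_plate", "z_min"] = self.z_min
        df.loc[df["state"] == "full_plate", "z_max"] = self.z_max
        return df


def _moments(x: np.ndarray) -> StateMoments:
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return StateMoments(mean=float(np.mean(x)), sd=sd, n=int(x.size))


def state_summary(
    values: np.ndarray,
    labels: np.ndarray | None = None,
    whale_id: str = "",
) -> ProfileSummary:
    """Mean/SD/n per reproductive state plus plate extremes and z extremes.

    ``labels`` entries must be in {pregnant, not_pregnant, unknown};
    with no labels (or all unknown) only the full-plate row is
    populated.
    """
    x = np.asarray(values, float)
    if labels is None:
        labels = np.full(x.shape, "unknown")
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(STATES)
    if bad:
        raise BaleendoError(f"unknown state labels {sorted(bad)}")
    by_state: dict[str, StateMoments] = {"full_plate": _moments(x)}
    for state in ("pregnant", "not_pregnant"):
        mask = labels == state
        if mask.any():
            by_state[state] = _moments(x[mask])
    z = zscores(x) if x.size >= 2 and np.std(x, ddof=1) > 0 else np.zeros_like(x)
    return ProfileSummary(
        whale_id=whale_id,
        by_state=by_state,
        plate_min=float(np.min(x)),
        plate_max=float(np.max(x)),
        plate_median=float(np.median(x)),
        z_min=float(np.min(z)),
        z_max=float(np.max(z)),
    )
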