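"""Isotope chronology: growth rate from annual delta-15N cycles.

Baleen grows continuously; as the whale alternates between summer
feeding and winter fasting/migration its tissue delta-15N oscillates, so
one cycle along the plate corresponds to one year of growth. The
distance between consecutive delta-15N peaks is therefore that year's
baleen growth rate (BGR, cm/yr), and integrating 1/rate from the
gumline outward converts any position into elapsed time before death.

Conventions: position 0 cm is the newest baleen at the gumline and is
dated to the day before the whale was found dead (unless an explicit
death date is supplied); dates decrease strictly with position; years
are 365.25 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import DAYS_PER_YEAR, RunConfig
from .errors import ChronologyError, InsufficientPeaksError
from .plate import BaleenPlate, WhaleRecord


def smooth_d15n(values: np.ndarray, window_neighbours: int = 4) -> np.ndarray:
    """Centred moving average over a sample and its nearest neighbours.

    ``window_neighbours`` is the number of neighbours included in
    addition to the sample itself (split evenly, so 4 neighbours means a
    5-point window). Near the edges the window shrinks symmetrically so
    it stays centred.
    """
    x = np.asarray(values, float)
    if x.size == 0 or np.all(np.isnan(x)):
        raise ChronologyError("cannot smooth an all-missing series")
    if window_neighbours % 2 != 0:
        raise ValueError("window_neighbours must be even (symmetric window)")
    half = window_neighbours // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.nanmean(x[i - k : i + k + 1])
    return out


def detect_peaks(
    positions: np.ndarray, smoothed: np.ndarray, min_separation_cm: float = 5.0
) -> np.ndarray:
    """Local maxima of the smoothed series, at least ``min_separation_cm`` apart.

    Candidates are interior local maxima (plate ends are excluded, since
    a partial cycle edge is not evidence of a peak). They are accepted
    greedily in order of descending height — ties broken toward the
    gumline — discarding any candidate within ``min_separation_cm`` of
    an already-accepted peak. Returned in ascending position.
    """
    pos = np.asarray(positions, float)
    y = np.asarray(smoothed, float)
    if pos.shape != y.shape:
        raise ValueError("positions and smoothed series must align")
    idx, _ = find_peaks(y)  # interior maxima; plateaus get one index
    if idx.size == 0:
        return np.empty(0)
    order = sorted(range(idx.size), key=lambda k: (-y[idx[k]], pos[idx[k]]))
    accepted: list[float] = []
    for k in order:
        p = pos[idx[k]]
        if all(abs(p - q) >= min_separation_cm for q in accepted):
            accepted.append(p)
    return np.sort(np.array(accepted))


def estimate_bgr(peak_positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Cycle-wise growth rates (cm/yr) and their arithmetic mean.

    Each inter-peak distance is one year of growth. Raises
    :class:`InsufficientPeaksError` with fewer than two peaks, in which
    case the caller should fall back to a configured default BGR.
    """
    peaks = np.asarray(peak_positions, float)
    if peaks.size < 2:
        raise InsufficientPeaksError(
            f"need >=2 peaks for a cycle-wise BGR, got {peaks.size}"
        )
    rates = np.diff(np.sort(peaks))
    return rates, float(np.mean(rates))


def zero_date(whale: WhaleRecord) -> dt.date:
    """Calendar date assigned to the 0-cm (gumline) point.

    The explicit death date wins when supplied (e.g. back-dated from
    foetal length and carcass condition); otherwise the day before the
    whale was found dead.
    """
    if whale.death_date is not None:
        return whale.death_date
    if whale.date_found is not None:
        return whale.date_found - dt.timedelta(days=1)
    raise ChronologyError(f"whale {whale.whale_id}: no death or found date")


@dataclass
class Chronology:
    """Monotone cm -> calendar-date map for one plate.

    The growth rate is piecewise constant: each inter-peak interval uses
    its own cycle rate, and the partial cycles before the first and
    after the last peak use the mean rate. ``date_of`` integrates
    1/rate from the gumline.
    """

    zero_date: dt.date
    peak_positions_cm: np.ndarray
    cycle_bgr_cm_per_yr: np.ndarray
    mean_bgr_cm_per_yr: float
    smoothed_d15n: np.ndarray | None = None
    smoothing_window: int = 5
    # segment boundaries/rates derived in __post_init__
    _bounds: np.ndarray = field(init=False, repr=False)
    _rates: np.ndarray = field(init=False, repr=False)
    _elapsed_at_bounds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        peaks = np.sort(np.asarray(self.peak_positions_cm, float))
        rates = np.asarray(self.cycle_bgr_cm_per_yr, float)
        if np.any(rates <= 0) or self.mean_bgr_cm_per_yr <= 0:
            raise ChronologyError("growth rates must be strictly positive")
        if peaks.size >= 2 and rates.size != peaks.size - 1:
            raise ChronologyError("need one cycle rate per inter-peak interval")
        if peaks.size >= 2:
            self._bounds = peaks
            self._rates = rates
        else:  # constant-rate timeline
            self._bounds = np.empty(0)
            self._rates = np.empty(0)
        # cumulative elapsed years at each bound, integrating from 0
        elapsed = []
        t = 0.0
        prev = 0.0
        for b, r in zip(self._bounds, np.concatenate([[self.mean_bgr_cm_per_yr], self._rates])):
            t += (b - prev) / r
            elapsed.append(t)
            prev = b
        self._elapsed_at_bounds = np.array(elapsed)

    @classmethod
    def from_constant_rate(
        cls, bgr_cm_per_yr: float, zero: dt.date, smoothing_window: int = 5
    ) -> "Chronology":
        return cls(
            zero_date=zero,
            peak_positions_cm=np.empty(0),
            cycle_bgr_cm_per_yr=np.empty(0),
            mean_bgr_cm_per_yr=float(bgr_cm_per_yr),
            smoothing_window=smoothing_window,
        )

    # -- the cm -> time map ---------------------------------------------
    def elapsed_years(self, position_cm) -> np.ndarray:
        """Years of growth between the gumline and ``position_cm``.

        Positions slightly below 0 (used when padding elevation runs by
        half a sample spacing) extrapolate with the first segment rate.
        """
        p = np.atleast_1d(np.asarray(position_cm, float))
        out = np.empty_like(p)
        for i, pi in enumerate(p):
            if self._bounds.size == 0:
                out[i] = pi / self.mean_bgr_cm_per_yr
                continue
            seg = np.searchsorted(self._bounds, pi, side="right")
            if seg == 0:
                out[i] = pi / self.mean_bgr_cm_per_yr
            else:
                base = self._elapsed_at_bounds[seg - 1]
                rate = (
                    self._rates[seg - 1]
                    if seg - 1 < self._rates.size
                    else self.mean_bgr_cm_per_yr
                )
                out[i] = base + (pi - self._bounds[seg - 1]) / rate
        return out if np.ndim(position_cm) else out[0]

    def date_of(self, position_cm) -> dt.date | list[dt.date]:
        """Estimated calendar date of growth at ``position_cm`` (day precision)."""
        el = np.atleast_1d(self.elapsed_years(position_cm))
        dates = [
            self.zero_date - dt.timedelta(days=round(e * DAYS_PER_YEAR)) for e in el
        ]
        return dates if np.ndim(position_cm) else dates[0]

    def cycle_index(self, position_cm) -> np.ndarray:
        """0-based growth-year index (newest year = 0) for each position."""
        el = np.atleast_1d(self.elapsed_years(position_cm))
        return np.floor(el).astype(int) if np.ndim(position_cm) else int(el[0])

    @property
    def span_years(self) -> float:
        """Total years covered by the fitted segments only (informational)."""
        if self._bounds.size == 0:
            return float("nan")
        return float(self._elapsed_at_bounds[-1])


def build_timeline(
    plate: BaleenPlate,
    whale: WhaleRecord,
    config: RunConfig | None = None,
) -> Chronology:
    """Full chronology for a plate: smooth, detect peaks, estimate BGR, date.

    Falls back to ``config.default_bgr_cm_per_yr`` (with <2 peaks or no
    isotope series), mirroring the practice of assigning young whales a
    fixed age-class BGR when no isotope data exist.
    """
    config = config or RunConfig()
    zero = zero_date(whale)
    if not plate.has_isotopes():
        return Chronology.from_constant_rate(config.default_bgr_cm_per_yr, zero)
    pos, d15n = plate.series("d15N_permil")
    smoothed = smooth_d15n(d15n, config.smoothing_window - 1)
    peaks = detect_peaks(pos, smoothed, config.peak_min_separation_cm)
    try:
        cycle_rates, mean_rate = estimate_bgr(peaks)
    except InsufficientPeaksError:
        chron = Chronology.from_constant_rate(config.default_bgr_cm_per_yr, zero)
        chron.smoothed_d15n = smoothed
        return chron
    return Chronology(
        zero_date=zero,
        peak_positions_cm=peaks,
        cycle_bgr_cm_per_yr=cycle_rates,
        mean_bgr_cm_per_yr=mean_rate,
        smoothed_d15n=smoothed,
        smoothing_window=config.smoothing_window,
    )


def annotate_plate(plate: BaleenPlate, chronology: Chronology) -> pd.DataFrame:
    """Per-sample table with smoothed_d15N, est_date and cycle_index columns."""
    df = plate.data.copy()
    if chronology.smoothed_d15n is not None:
        pos, _ = plate.series("d15N_permil")
        sm = pd.Series(chronology.smoothed_d15n, index=pos)
        df["smoothed_d15N"] = df["position_cm"].map(sm)
    else:
        df["smoothed_d15N"] = np.nan
    df["est_date"] = [d.isoformat() for d in chronology.date_of(df["position_cm"].to_numpy())]
    df["cycle_index"] = chronology.cycle_index(df["position_cm"].to_numpy())
    return df
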