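"""Pregnancy calling from progesterone profiles.

The diagnostic rule: a contiguous elevation at least 100% above
baseline (i.e. at least twice baseline) sustained for more than 10
months of baleen growth is called a full-term pregnancy. A qualifying
single sample is a spike; anything in between is a short elevation
(luteal phase, estrous, pseudopregnancy or early failed pregnancy —
indistinguishable here by design).

Conceptions can also be dated from the foetus found at necropsy, via a
monotone foetal length -> gestational age model, with month-of-year
arithmetic (the population's conceptions and calvings cluster in
December-January).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DAYS_PER_MONTH, RunConfig
from .chronology import Chronology
from .errors import BaleendoError
from .profile import percent_above

CLASSIFICATIONS = ("full_term_pregnancy", "short_elevation", "spike")


def add_months(d: dt.date, months: float) -> dt.date:
    """Calendar-month arithmetic; fractional months as 365.25/12-day blocks."""
    whole = int(months // 1) if months >= 0 else -int((-months) // 1)
    frac = months - whole
    month0 = d.month - 1 + whole
    year = d.year + month0 // 12
    month = month0 % 12 + 1
    day = min(d.day, _days_in_month(year, month))
    out = dt.date(year, month, day)
    if frac:
        out += dt.timedelta(days=round(frac * DAYS_PER_MONTH))
    return out


def _days_in_month(year: int, month: int) -> int:
    nxt = dt.date(year + month // 12, month % 12 + 1, 1)
    return (nxt - dt.date(year, month, 1)).days


def months_between(earlier: dt.date, later: dt.date) -> float:
    """Signed interval in average calendar months (365.25/12 days)."""
    return (later - earlier).days / DAYS_PER_MONTH


@dataclass
class ElevationRun:
    """A maximal run of consecutive above-threshold samples, dated."""

    start_cm: float
    end_cm: float
    start_date: dt.date  # older endpoint (corresponds to end_cm)
    end_date: dt.date  # newer endpoint (corresponds to start_cm)
    duration_months: float
    peak_value_ng_g: float
    peak_percent_above_baseline: float
    n_samples: int
    classification: str = "short_elevation"

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("a run needs at least one sample")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass
class PregnancyCall:
    """A dated pregnancy: conception plus projected or observed birth."""

    conception_date: dt.date
    birth_date: dt.date
    source: str  # {hormone_profile, foetus_at_necropsy, sighting}
    gestation_months: float = 12.0
    run: ElevationRun | None = None

    def __post_init__(self):
        if self.source not in {"hormone_profile", "foetus_at_necropsy", "sighting"}:
            raise ValueError(f"unknown call source {self.source!r}")


@dataclass
class FoetalGrowthModel:
    """Monotone piecewise-linear foetal length (cm) -> age (months).

    Default knots interpolate the two case-study calibration pairs
    (39.2 cm at 4 months, 168 cm at 8 months) and extend through an
    early-gestation point and a neonate length from the growth-rate
    literature. All knots are configurable.
    """

    knots: tuple[tuple[float, float], ...] = (
        (0.0, 0.5),
        (39.2, 4.0),
        (168.0, 8.0),
        (450.0, 12.0),
    )

    def __post_init__(self):
        lengths = [k[0] for k in self.knots]
        ages = [k[1] for k in self.knots]
        if sorted(lengths) != lengths or len(set(lengths)) != len(lengths):
            raise ValueError("knot lengths must be strictly increasing")
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ValueError("knot ages must be strictly increasing")
        if min(ages) < 0:
            raise ValueError("ages must be non-negative")

    def age_months(self, foetal_length_cm: float) -> float:
        lengths = np.array([k[0] for k in self.knots])
        ages = np.array([k[1] for k in self.knots])
        if not lengths[0] <= foetal_length_cm <= lengths[-1]:
            raise BaleendoError(
                f"foetal length {foetal_length_cm} cm outside calibrated range "
                f"[{lengths[0]}, {lengths[-1]}] cm"
            )
        return float(np.interp(foetal_length_cm, lengths, ages))


# ---------------------------------------------------------------------------
# run detection and classification
# ---------------------------------------------------------------------------

def find_runs(
    values: np.ndarray,
    positions: np.ndarray,
    timeline: Chronology,
    baseline: float,
    threshold_percent: float = 100.0,
    dip_tolerance: bool = True,
    sample_spacing_cm: float | None = None,
) -> list[ElevationRun]:
    """Maximal runs of consecutive samples at/above the elevation threshold.

    One interior sub-threshold sample is tolerated when both neighbours
    qualify (assay-noise tolerance; configurable off). Runs are dated
    through the timeline; the duration spans the first to last
    qualifying sample plus half a sample spacing on each side, because
    each subsample integrates an interval of growth.
    """
    x = np.asarray(values, float)
    pos = np.asarray(positions, float)
    if baseline <= 0:
        raise BaleendoError("baseline must be strictly positive")
    qualifies = percent_above(x, baseline) >= threshold_percent
    mask = qualifies.copy()
    if dip_tolerance:
        for i in range(1, len(mask) - 1):
            if not qualifies[i] and qualifies[i - 1] and qualifies[i + 1]:
                mask[i] = True
    if sample_spacing_cm is None:
        sample_spacing_cm = float(np.median(np.diff(pos))) if len(pos) > 1 else 2.0
    runs: list[ElevationRun] = []
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        seg_vals = x[seg]
        start_cm, end_cm = float(pos[i]), float(pos[j])
        half = sample_spacing_cm / 2.0
        older = timeline.date_of(end_cm + half)
        newer = timeline.date_of(start_cm - half)  # may extrapolate past the gumline
        duration = months_between(older, newer)
        k = int(np.argmax(seg_vals))
        runs.append(
            ElevationRun(
                start_cm=start_cm,
                end_cm=end_cm,
                start_date=timeline.date_of(end_cm),
                end_date=timeline.date_of(start_cm),
                duration_months=duration,
                peak_value_ng_g=float(seg_vals[k]),
                peak_percent_above_baseline=float(percent_above(seg_vals[k], baseline)),
                n_samples=int(qualifies[seg].sum()),
            )
        )
        i = j + 1
    return runs


def classify_run(run: ElevationRun, min_months: float = 10.0) -> str:
    """Spike (single sample), full-term pregnancy (> min duration) or short."""
    if run.n_samples == 1:
        return "spike"
    if run.duration_months > min_months:
        return "full_term_pregnancy"
    return "short_elevation"


def classify_runs(runs: list[ElevationRun], min_months: float = 10.0) -> list[ElevationRun]:
    return [replace(r, classification=classify_run(r, min_months)) for r in runs]


def estimate_calling_baseline(
    values: np.ndarray,
    positions: np.ndarray,
    timeline: Chronology,
    config: RunConfig | None = None,
    max_iter: int = 25,
    rel_tol: float = 1e-3,
    start_quantile: float = 0.25,
) -> float:
    """Baseline for calling, by iterative exclusion of elevation runs.

    Starts from a low quantile of the profile (so that an inflated
    plate-wide mean cannot hide true elevations even when most of the
    plate is pregnancy-elevated), detects elevation runs at the current
    threshold, recomputes the baseline as the mean of the samples
    outside any run and repeats to convergence. Samples immediately
    adjacent to a run are excluded too: each subsample integrates an
    interval of growth, so run neighbours are partially elevated by
    construction. Without labels this converges to the non-pregnant
    mean provided at least roughly a quarter of the plate is
    non-pregnant.
    """
    config = config or RunConfig()
    x = np.asarray(values, float)
    pos = np.asarray(positions, float)
    spacing = float(np.median(np.diff(pos))) if len(pos) > 1 else 2.0
    base = float(np.quantile(x, start_quantile))
    if base <= 0:
        base = float(np.mean(x[x > 0])) if (x > 0).any() else 1e-9
    for _ in range(max_iter):
        runs = find_runs(
            x, pos, timeline, base,
            threshold_percent=config.elevation_threshold_percent,
            dip_tolerance=config.dip_tolerance,
        )
        excluded = np.zeros_like(x, bool)
        for r in runs:
            excluded |= (pos >= r.start_cm - 1.5 * spacing) & (pos <= r.end_cm + 1.5 * spacing)
        if excluded.all():  # pathological: keep the current baseline
            break
        new = float(np.mean(x[~excluded]))
        if abs(new - base) <= rel_tol * base:
            base = new
            break
        base = new
    return base


# ---------------------------------------------------------------------------
# dating conceptions and births
# ---------------------------------------------------------------------------

def conception_from_foetus(
    foetal_length_cm: float,
    death_date: dt.date,
    model: FoetalGrowthModel | None = None,
    gestation_months: float = 12.0,
) -> PregnancyCall:
    """Back-date conception from the foetus found at necropsy.

    Gestational age is rounded to whole months and subtracted with
    month-of-year arithmetic, matching month-level reporting.
    """
    model = model or FoetalGrowthModel()
    age = round(model.age_months(foetal_length_cm))
    conception = add_months(dt.date(death_date.year, death_date.month, 1), -age)
    return PregnancyCall(
        conception_date=conception,
        birth_date=project_birth(conception, gestation_months),
        source="foetus_at_necropsy",
        gestation_months=gestation_months,
    )


def project_birth(conception: dt.date, gestation_months: float = 12.0) -> dt.date:
    """Projected birth date = conception + gestation (calendar months)."""
    return add_months(conception, gestation_months)


def calls_from_runs(
    runs: list[ElevationRun], gestation_months: float = 12.0
) -> list[PregnancyCall]:
    """One call per full-term run: conception at elevation onset."""
    calls = []
    for r in runs:
        if r.classification != "full_term_pregnancy":
            continue
        calls.append(
            PregnancyCall(
                conception_date=r.start_date,
                birth_date=project_birth(r.start_date, gestation_months),
                source="hormone_profile",
                gestation_months=gestation_months,
                run=r,
            )
        )
    return calls


def birth_from_calf_sighting(
    sighting_date: dt.date, calving_month: int = 1
) -> dt.date:
    """Birth inferred from a neonatal-calf sighting.

    Births cluster at the anchor calving month; a calf seen later in
    the year is assigned a birth at that month of the same year (or the
    prior year if the sighting precedes the calving month).
    """
    year = sighting_date.year
    if sighting_date.month < calving_month:
        year -= 1
    return dt.date(year, calving_month, 15)


@dataclass
class CalvingInterval:
    earlier_birth: dt.date
    later_birth: dt.date
    exact_years: float
    years: int  # rounded for reporting


def calving_intervals(birth_dates: list[dt.date]) -> list[CalvingInterval]:
    """Successive inter-birth intervals; exact value kept, whole years reported."""
    births = sorted(birth_dates)
    out = []
    for a, b in zip(births, births[1:]):
        exact = (b - a).days / 365.25
        out.append(CalvingInterval(a, b, exact, int(round(exact))))
    return out


def label_status(
    positions: np.ndarray, timeline: Chronology, calls: list[PregnancyCall]
) -> np.ndarray:
    """Per-sample status: pregnant iff the estimated growth date falls
    within [conception, birth] of any call."""
    dates = timeline.date_of(np.asarray(positions, float))
    labels = np.full(len(dates), "not_pregnant", dtype=object)
    for i, d in enumerate(dates):
        for c in calls:
            if c.conception_date <= d <= c.birth_date:
                labels[i] = "pregnant"
                break
    return labels
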