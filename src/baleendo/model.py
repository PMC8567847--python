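"""Top-level Model/Results objects chaining the pipeline stages.

``BaleenPregnancyModel`` is built from one plate plus whale metadata;
``fit()`` runs chronology -> baseline -> elevation runs -> pregnancy
calls -> state labels -> profile summary and returns a
``BaleenPregnancyResults`` carrying every intermediate product, a
``summary()`` table and writers for the delimited outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import caller as _caller
from . import profile as _profile
from .chronology import Chronology, annotate_plate, build_timeline
from .config import RunConfig
from .errors import PipelineError
from .plate import BaleenPlate, SightingEvent, WhaleRecord


@dataclass
class BaleenPregnancyResults:
    """Everything a fitted plate analysis produced."""

    whale_id: str
    config: RunConfig
    chronology: Chronology
    calling_baseline_ng_g: float | None
    baselines: dict[str, float]
    runs: list[_caller.ElevationRun]
    calls: list[_caller.PregnancyCall]
    labels: np.ndarray | None
    profile: _profile.ProfileSummary | None
    calving: list[_caller.CalvingInterval]
    annotated: pd.DataFrame
    run_log: list[str] = field(default_factory=list)

    # -- tables ----------------------------------------------------------
    def calls_table(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            r = c.run
            rows.append(
                {
                    "whale_id": self.whale_id,
                    "source": c.source,
                    "conception_date": c.conception_date.isoformat(),
                    "birth_date": c.birth_date.isoformat(),
                    "gestation_months": c.gestation_months,
                    "start_cm": np.nan if r is None else r.start_cm,
                    "end_cm": np.nan if r is None else r.end_cm,
                    "duration_months": np.nan if r is None else r.duration_months,
                    "peak_ng_g": np.nan if r is None else r.peak_value_ng_g,
                    "peak_percent_above": np.nan if r is None else r.peak_percent_above_baseline,
                }
            )
        return pd.DataFrame(rows)

    def runs_table(self) -> pd.DataFrame:
        rows = [
            {
                "whale_id": self.whale_id,
                "start_cm": r.start_cm,
                "end_cm": r.end_cm,
                "start_date": r.start_date.isoformat(),
                "end_date": r.end_date.isoformat(),
                "duration_months": r.duration_months,
                "peak_ng_g": r.peak_value_ng_g,
                "peak_percent_above": r.peak_percent_above_baseline,
                "n_samples": r.n_samples,
                "classification": r.classification,
            }
            for r in self.runs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted plate."""
        chron = self.chronology
        lines = [
            f"Baleen pregnancy analysis — {self.whale_id}",
            "=" * 52,
            f"config hash: {self.config.config_hash()}",
            f"zero-cm date: {chron.zero_date.isoformat()}",
        ]
        if chron.peak_positions_cm.size:
            peaks = ", ".join(f"{p:g}" for p in chron.peak_positions_cm)
            cycles = ", ".join(f"{r:g}" for r in chron.cycle_bgr_cm_per_yr)
            lines += [
                f"d15N peaks (cm): {peaks}",
                f"cycle growth rates (cm/yr): {cycles}",
            ]
        lines.append(f"mean growth rate: {chron.mean_bgr_cm_per_yr:.1f} cm/yr")
        for method, value in self.baselines.items():
            lines.append(f"baseline [{method}]: {value:.2f} ng/g")
        if self.calling_baseline_ng_g is not None:
            lines.append(f"calling baseline (run-excluded): {self.calling_baseline_ng_g:.2f} ng/g")
        lines.append(f"elevation runs: {len(self.runs)}")
        for r in self.runs:
            lines.append(
                f"  {r.start_cm:g}-{r.end_cm:g} cm  {r.start_date}..{r.end_date}  "
                f"{r.duration_months:.1f} mo  peak {r.peak_value_ng_g:.0f} ng/g "
                f"({r.peak_percent_above_baseline:.0f}% above)  -> {r.classification}"
            )
        lines.append(f"pregnancy calls: {len(self.calls)}")
        for c in self.calls:
            lines.append(
                f"  conception {c.conception_date} -> birth {c.birth_date} [{c.source}]"
            )
        for iv in self.calving:
            lines.append(
                f"calving interval: {iv.earlier_birth} -> {iv.later_birth} = "
                f"{iv.exact_years:.2f} yr (reported {iv.years} yr)"
            )
        if self.profile is not None:
            lines.append("")
            lines.append(self.profile.to_frame().to_string(index=False))
        return "\n".join(lines)

    def write_tables(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.annotated.to_csv(out / f"{self.whale_id}_annotated.csv", index=False)
        self.calls_table().to_csv(out / f"{self.whale_id}_calls.csv", index=False)
        self.runs_table().to_csv(out / f"{self.whale_id}_runs.csv", index=False)
        if self.profile is not None:
            self.profile.to_frame().to_csv(out / f"{self.whale_id}_summary.csv", index=False)
        (out / f"{self.whale_id}_run.log").write_text("\n".join(self.run_log) + "\n")

    def plot_profile(self, ax=None):
        """Progesterone (and smoothed d15N) against estimated date."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.annotated
        dates = pd.to_datetime(df["est_date"])
        ax.plot(dates, df["progesterone_ng_g"], "o-", color="tab:blue", label="progesterone")
        for c in self.calls:
            ax.axvspan(
                pd.Timestamp(c.conception_date), pd.Timestamp(c.birth_date),
                alpha=0.15, color="grey",
            )
        ax.set_xlabel("estimated date of growth")
        ax.set_ylabel("progesterone (ng/g)")
        ax.set_title(self.whale_id)
        ax.legend(loc="upper left")
        return ax


class BaleenPregnancyModel:
    """Pregnancy-history model for one baleen plate.

    Parameters
    ----------
    plate : BaleenPlate
    whale : WhaleRecord
        Supplies the zero-cm date and, when present, the necropsy
        foetal length for back-dating the final conception.
    sightings : list of SightingEvent, optional
        Calf sightings anchor observed births for calving intervals.
    config : RunConfig, optional
    """

    def __init__(
        self,
        plate: BaleenPlate,
        whale: WhaleRecord,
        sightings: list[SightingEvent] | None = None,
        config: RunConfig | None = None,
    ):
        self.plate = plate
        self.whale = whale
        self.sightings = sightings or []
        self.config = config or RunConfig()

    @classmethod
    def from_tables(
        cls,
        plate_path: str | Path,
        whale: WhaleRecord,
        sightings: list[SightingEvent] | None = None,
        config: RunConfig | None = None,
    ) -> "BaleenPregnancyModel":
        from .io import read_plate_table

        return cls(read_plate_table(plate_path, whale.whale_id), whale, sightings, config)

    def fit(self) -> BaleenPregnancyResults:
        cfg = self.config
        log = [f"config {cfg.config_hash()}", f"plate {self.plate.whale_id} n={self.plate.n_samples}"]

        def stage(name, fn, *args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.append(f"{name}: ok")
            return out

        chron = stage("chronology", build_timeline, self.plate, self.whale, cfg)

        runs: list[_caller.ElevationRun] = []
        calls: list[_caller.PregnancyCall] = []
        labels = None
        summary = None
        baselines: dict[str, float] = {}
        calling_base = None
        if self.plate.has_progesterone():
            pos, p4 = self.plate.series("progesterone_ng_g")
            if cfg.refine_baseline:
                calling_base = stage(
                    "baseline", _caller.estimate_calling_baseline, p4, pos, chron, cfg
                )
            else:
                calling_base = stage("baseline", _profile.baseline, p4, cfg.baseline_method)
            runs = stage(
                "find_runs", _caller.find_runs, p4, pos, chron, calling_base,
                cfg.elevation_threshold_percent, cfg.dip_tolerance,
            )
            runs = _caller.classify_runs(runs, cfg.min_pregnancy_duration_months)
            calls = _caller.calls_from_runs(runs, cfg.gestation_months)
            if self.whale.foetal_length_cm is not None:
                foetal_call = stage(
                    "foetal_dating",
                    _caller.conception_from_foetus,
                    self.whale.foetal_length_cm,
                    chron.zero_date,
                    gestation_months=cfg.gestation_months,
                )
                # drop hormone calls that re-detect the same ongoing pregnancy
                calls = [
                    c for c in calls
                    if not _overlaps(c, foetal_call)
                ] + [foetal_call]
            calls.sort(key=lambda c: c.conception_date)
            labels = stage("label_status", _caller.label_status, pos, chron, calls)
            summary = stage(
                "state_summary", _profile.state_summary, p4, labels, self.plate.whale_id
            )
            baselines["full_plate_mean"] = _profile.baseline(p4, "full_plate_mean")
            baselines["full_plate_median"] = _profile.baseline(p4, "full_plate_median")
            if labels is not None and (labels == "not_pregnant").any():
                baselines["nonpregnant_mean"] = _profile.baseline(p4, "nonpregnant_mean", labels)

        births = [c.birth_date for c in calls if c.birth_date <= _horizon(chron)]
        births += [
            _caller.birth_from_calf_sighting(s.date, cfg.anchor_month)
            for s in self.sightings
            if s.with_calf
        ]
        # keep projected births too: the most recent pregnancy may end after death
        births += [c.birth_date for c in calls if c.birth_date > _horizon(chron)]
        births = _dedupe_births(births)
        calving = _caller.calving_intervals(births) if len(births) >= 2 else []

        annotated = annotate_plate(self.plate, chron)
        if labels is not None:
            lab = pd.Series(labels, index=self.plate.series("progesterone_ng_g")[0])
            annotated["status"] = annotated["position_cm"].map(lab)
        log.append(f"calls: {len(calls)}; runs: {len(runs)}")
        return BaleenPregnancyResults(
            whale_id=self.plate.whale_id,
            config=cfg,
            chronology=chron,
            calling_baseline_ng_g=calling_base,
            baselines=baselines,
            runs=runs,
            calls=calls,
            labels=labels,
            profile=summary,
            calving=calving,
            annotated=annotated,
            run_log=log,
        )


def _overlaps(a: _caller.PregnancyCall, b: _caller.PregnancyCall) -> bool:
    return a.conception_date <= b.birth_date and b.conception_date <= a.birth_date


def _horizon(chron: Chronology) -> dt.date:
    return chron.zero_date


def _dedupe_births(births: list[dt.date], window_days: int = 240) -> list[dt.date]:
    """Collapse birth dates within ~8 months of each other (same calf)."""
    out: list[dt.date] = []
    for b in sorted(births):
        if out and (b - out[-1]).days < window_days:
            continue
        out.append(b)
    return out


def run_pipeline(
    config: RunConfig,
    plate: BaleenPlate,
    whale: WhaleRecord,
    sightings: list[SightingEvent] | None = None,
) -> BaleenPregnancyResults:
    """Functional entry point: build the model and fit it."""
    return BaleenPregnancyModel(plate, whale, sightings, config).fit()
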