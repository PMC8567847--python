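"""Run configuration shared by the pipeline stages.

Defaults follow the published humpback case-study protocol: 5-point
(self + 4 nearest neighbours) smoothing of the nitrogen isotope series,
5 cm minimum peak separation, a pregnancy threshold of 100% above
baseline sustained for more than 10 months, a 12-month gestation with
December-January conceptions/calvings, and the methanol extraction
mass balance (75.0 mg powder, 4.00 ml solvent, 3.00 ml aliquot,
0.50 ml reconstitution).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


@dataclass
class ExtractionParams:
    """Methanol extraction constants used for the ng/g mass balance."""

    powder_mass_mg: float = 75.0
    solvent_volume_ml: float = 4.00
    aliquot_volume_ml: float = 3.00
    reconstitution_volume_ml: float = 0.50

    def __post_init__(self):
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all extraction volumes/masses must be positive")
        if self.aliquot_volume_ml > self.solvent_volume_ml:
            raise ValueError("aliquot volume cannot exceed solvent volume")


@dataclass
class RunConfig:
    """Tunable parameters for a pipeline run.

    All thresholds are strictly positive; the documented defaults are
    the case-study values.
    """

    # isotope chronology
    smoothing_window: int = 5  # centred points: self + 4 nearest neighbours
    peak_min_separation_cm: float = 5.0
    default_bgr_cm_per_yr: float = 20.0  # fallback when no isotope series
    # hormone profile / pregnancy calling
    baseline_method: str = "full_plate_mean"
    refine_baseline: bool = True  # iteratively exclude elevation runs
    elevation_threshold_percent: float = 100.0
    min_pregnancy_duration_months: float = 10.0
    dip_tolerance: bool = True  # allow one interior sub-threshold sample
    gestation_months: float = 12.0
    anchor_month: int = 1  # conception/calving month for this population
    # assay reduction
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    dilution_steps: tuple[int, ...] = (4, 16, 64)
    rebound_percent: float = 5.0  # percent bound below which to re-dilute
    max_duplicate_cv_percent: float = 10.0
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        positive = {
            "smoothing_window": self.smoothing_window,
            "peak_min_separation_cm": self.peak_min_separation_cm,
            "default_bgr_cm_per_yr": self.default_bgr_cm_per_yr,
            "elevation_threshold_percent": self.elevation_threshold_percent,
            "min_pregnancy_duration_months": self.min_pregnancy_duration_months,
            "gestation_months": self.gestation_months,
            "rebound_percent": self.rebound_percent,
            "max_duplicate_cv_percent": self.max_duplicate_cv_percent,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd (centred window)")
        if not 1 <= self.anchor_month <= 12:
            raise ValueError("anchor_month must be in 1..12")
        if self.baseline_method not in {
            "full_plate_mean",
            "nonpregnant_mean",
            "full_plate_median",
        }:
            raise ValueError(f"unknown baseline_method {self.baseline_method!r}")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilution_steps"] = list(self.dilution_steps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "extraction" in d and isinstance(d["extraction"], dict):
            d["extraction"] = ExtractionParams(**d["extraction"])
        if "dilution_steps" in d:
            d["dilution_steps"] = tuple(d["dilution_steps"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML (or JSON, which is a YAML subset) key-value file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
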