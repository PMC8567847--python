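"""Reference values from the published four-whale humpback case study.

These are the printed summary values (per-whale tables and results
text) of the study that established the pregnancy-calling rule; the raw
per-sample series were never released. They serve as worked-example
inputs and as cross-checks for the arithmetic in this package. Where
the results text and the summary table disagree (different sample
subsets), both values are kept and neither is adjudicated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass


@dataclass(frozen=True)
class WhaleSummary:
    whale_id: str
    sex: str
    age_years: float
    baleen_length_cm: float
    body_length_m: float
    n_samples: int
    # full-plate progesterone moments (ng/g)
    plate_mean: float
    plate_sd: float
    plate_median: float | None
    plate_min: float
    plate_max: float
    # per-state moments from the summary table (ng/g), None when unlabelled
    pregnant_mean: float | None = None
    pregnant_sd: float | None = None
    pregnant_n: int | None = None
    nonpregnant_mean: float | None = None
    nonpregnant_sd: float | None = None
    nonpregnant_n: int | None = None
    # alternative group means from the results text (different subset)
    pregnant_mean_text: float | None = None
    nonpregnant_mean_text: float | None = None
    nonpregnant_sd_text: float | None = None
    # printed z-score extremes
    z_min: float | None = None
    z_max: float | None = None


WHALES: dict[str, WhaleSummary] = {
    "SEAK 68": WhaleSummary(
        whale_id="SEAK 68", sex="female", age_years=44.5,
        baleen_length_cm=66.0, body_length_m=13.87, n_samples=30,
        plate_mean=218.09, plate_sd=139.77, plate_median=173.15,
        plate_min=40.78, plate_max=484.14,
        pregnant_mean=352.09, pregnant_sd=111.52, pregnant_n=11,
        nonpregnant_mean=140.51, nonpregnant_sd=85.02, nonpregnant_n=19,
        pregnant_mean_text=361.88,
        nonpregnant_mean_text=132.44, nonpregnant_sd_text=79.64,
        z_min=-1.27, z_max=1.90,
    ),
    "SEAK 1473": WhaleSummary(
        whale_id="SEAK 1473", sex="female", age_years=13.0,
        baleen_length_cm=64.0, body_length_m=12.5, n_samples=31,
        plate_mean=263.03, plate_sd=275.20, plate_median=184.85,
        plate_min=1.09, plate_max=966.46,
        pregnant_mean=600.27, pregnant_sd=159.88, pregnant_n=10,
        nonpregnant_mean=102.44, nonpregnant_sd=134.74, nonpregnant_n=21,
        pregnant_mean_text=524.96,
        nonpregnant_mean_text=104.44, nonpregnant_sd_text=140.86,
        z_min=-0.95, z_max=2.56,
    ),
    "Spinnaker": WhaleSummary(
        whale_id="Spinnaker", sex="female", age_years=11.0,
        baleen_length_cm=66.0, body_length_m=10.79, n_samples=33,
        plate_mean=21.45, plate_sd=14.97, plate_median=None,
        plate_min=2.61, plate_max=73.87, z_min=-1.3, z_max=3.5,
    ),
    "Lighthouse": WhaleSummary(
        whale_id="Lighthouse", sex="male", age_years=3.0,
        baleen_length_cm=45.0, body_length_m=10.97, n_samples=23,
        plate_mean=24.97, plate_sd=14.99, plate_median=None,
        plate_min=10.50, plate_max=74.88, z_min=-0.16, z_max=3.3,
    ),
}

#: Inter-peak distances (cm) between successive annual d15N maxima,
#: oldest-to-newest irrelevant here; each distance is one year's growth.
CYCLE_DISTANCES_CM: dict[str, list[float]] = {
    "SEAK 68": [20.0, 16.0, 15.0],
    "SEAK 1473": [18.0, 22.0],
}

#: Necropsy foetal lengths and back-dated death dates.
FOETAL_LENGTH_CM = {"SEAK 68": 39.2, "SEAK 1473": 168.0}
FOETAL_AGE_MONTHS = {"SEAK 68": 4.0, "SEAK 1473": 8.0}
DEATH_DATE = {
    # found July 2001; gumline dated to the day before discovery
    "SEAK 68": dt.date(2001, 7, 14),
    # found May 2010 after overwintering on the beach; death back-dated
    "SEAK 1473": dt.date(2009, 10, 1),
}
DATE_FOUND = {"SEAK 68": dt.date(2001, 7, 15), "SEAK 1473": dt.date(2010, 5, 15)}

#: First-pregnancy births inferred from calf sightings (winter calving).
OBSERVED_BIRTH = {
    "SEAK 68": dt.date(1999, 12, 15),  # calf seen summer 2000
    "SEAK 1473": dt.date(2007, 1, 15),  # calf seen 2007
}

#: Typical adult baleen growth-rate band (cm/yr) used for sampling design.
TYPICAL_BGR_RANGE = (16.0, 24.0)
SAMPLE_SPACING_CM = 2.0
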