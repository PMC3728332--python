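"""Study configuration.

All thresholds and constants that parameterize the analysis live here so
that QC, correction and classification stages share one source of truth.
Units: areas in km^2, lengths in cm, weights in g, ping intervals in
seconds, thresholds in percent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

HABITATS = ("NR", "AR", "SW", "CV")
"""Habitat zones: natural reef, artificial reef, harbor seawalls, and the
Cote Vermeille rocky coast."""


@dataclass
class StudyConfig:
    """Constants of the monitoring study and analysis thresholds.

    Defaults describe the Leucate - Le Barcares artificial reef system and
    the Cape Leucate natural reef: receiver-covered sampling areas of
    1.69 km^2 (AR) and 0.75 km^2 (NR), a post-release mortality screening
    window (strong-current period) of 2011-05-30 to 2011-06-22 with a
    20-day minimum detection period, and the behavioral classification
    thresholds (transient below 50% detection rate, resident at >= 70%
    residency index in a single habitat).
    """

    habitat_area: dict[str, float] = field(
        default_factory=lambda: {"AR": 1.69, "NR": 0.75}
    )
    mortality_window: tuple[dt.date, dt.date] = (
        dt.date(2011, 5, 30),
        dt.date(2011, 6, 22),
    )
    mortality_min_days: int = 20
    transient_dr_threshold: float = 50.0
    resident_ri_threshold: float = 70.0
    study_latitude: float = 42.8
    study_longitude: float = 3.05
    utc_offset_hours: float = 2.0  # local summer time of the study area
    significance_level: float = 0.95
    p_floor: float = 0.05  # floor on control detection probability

    def __post_init__(self) -> None:
        for hab, area in self.habitat_area.items():
            if area <= 0:
                raise ValueError(f"habitat area must be > 0, got {hab}={area}")
        for name in ("transient_dr_threshold", "resident_ri_threshold"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if not 0 < self.significance_level < 1:
            raise ValueError("significance_level must be in (0, 1)")
        if not 0 < self.p_floor < 1:
            raise ValueError("p_floor must be in (0, 1)")
        if self.mortality_window[0] > self.mortality_window[1]:
            raise ValueError("mortality_window start after end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mortality_window" in raw:
            raw["mortality_window"] = tuple(
                v if isinstance(v, dt.date) else dt.date.fromisoformat(v)
                for v in raw["mortality_window"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "habitat_area": dict(self.habitat_area),
            "mortality_window": [d.isoformat() for d in self.mortality_window],
            "mortality_min_days": self.mortality_min_days,
            "transient_dr_threshold": self.transient_dr_threshold,
            "resident_ri_threshold": self.resident_ri_threshold,
            "study_latitude": self.study_latitude,
            "study_longitude": self.study_longitude,
            "utc_offset_hours": self.utc_offset_hours,
            "significance_level": self.significance_level,
            "p_floor": self.p_floor,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
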