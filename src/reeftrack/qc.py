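"""Detection-log quality control.

Two cleaning rules are applied before any analysis:

1. *Single daily detections* — a tag heard exactly once on a local
   calendar day (pooled across receivers) is most plausibly a false
   detection from code collision between transmitters; that lone record
   is dropped.  The rule is evaluated per tag-day, not per receiver-day,
   because collisions are tag-level events.
2. *Presumed post-release mortality* — fish released during the
   strong-current window whose detection period stayed below the minimum
   and that were only ever heard by their release receiver are treated
   as tagging mortalities and excluded from analysis.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .io import local_day

NEVER_DETECTED = "never_detected"
PRESUMED_DEAD = "presumed_dead"


@dataclasses.dataclass
class QcReport:
    n_input_records: int = 0
    n_removed_single_daily: int = 0
    excluded_fish: dict[str, str] = dataclasses.field(default_factory=dict)
    n_retained_fish: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def remove_single_daily_detections(
    detections: pd.DataFrame, utc_offset_hours: float = 2.0
) -> tuple[pd.DataFrame, QcReport]:
    """Drop every detection that is its tag's only one on a local day.

    Idempotent: days left with >= 2 detections are never reduced to one,
    and a day with one detection loses it entirely, so a second pass
    removes nothing.
    """
    report = QcReport(n_input_records=len(detections))
    if detections.empty:
        return detections.copy(), report
    day = local_day(detections["timestamp"], utc_offset_hours)
    per_day = detections.groupby([detections["tag_id"], day])["timestamp"].transform(
        "size"
    )
    keep = per_day > 1
    report.n_removed_single_daily = int((~keep).sum())
    return detections[keep].reset_index(drop=True), report


def release_receiver(
    fish_detections: pd.DataFrame, utc_offset_hours: float = 2.0
) -> str | None:
    """Receiver attributed to the release site of one fish.

    Release coordinates are not part of the data model, so the release
    receiver is taken as the receiver of the fish's first detection
    (detections sorted by time); ``None`` when the fish was never heard.
    """
    if fish_detections.empty:
        return None
    first = fish_detections.sort_values("timestamp").iloc[0]
    return str(first["receiver_id"])


def exclude_presumed_dead(
    tags: pd.DataFrame,
    detections: pd.DataFrame,
    cfg: StudyConfig,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the mortality-screening rule to the fish tag set.

    A fish is excluded iff its release date falls inside
    ``cfg.mortality_window`` AND its detection period (first to last
    detection, inclusive local days) is below ``cfg.mortality_min_days``
    AND all of its detections came from its release receiver.  Fish with
    zero detections are flagged ``never_detected`` instead.  Control tags
    pass through untouched.

    Returns the retained tag table (controls + surviving fish) and a
    :class:`QcReport`.
    """
    report = QcReport(n_input_records=len(detections))
    fish = tags[tags["kind"] == "fish"]
    w0, w1 = cfg.mortality_window
    excluded: dict[str, str] = {}
    for _, row in fish.iterrows():
        det = detections[detections["tag_id"] == row["tag_id"]]
        if det.empty:
            excluded[row["tag_id"]] = NEVER_DETECTED
            continue
        rel_date = pd.Timestamp(row["release_datetime"]).date()
        if not (w0 <= rel_date <= w1):
            continue
        days = local_day(det["timestamp"], cfg.utc_offset_hours)
        dp = (days.max() - days.min()).days + 1
        if dp >= cfg.mortality_min_days:
            continue
        if det["receiver_id"].nunique() == 1 and (
            det["receiver_id"].iloc[0] == release_receiver(det, cfg.utc_offset_hours)
        ):
            excluded[row["tag_id"]] = PRESUMED_DEAD
    dead = {t for t, r in excluded.items() if r == PRESUMED_DEAD}
    retained = tags[(tags["kind"] == "control") | ~tags["tag_id"].isin(dead)]
    report.excluded_fish = excluded
    report.n_retained_fish = int((retained["kind"] == "fish").sum())
    return retained.reset_index(drop=True), report
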