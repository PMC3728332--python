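"""Per-fish residency metrics, behavioral classification and connectivity.

Definitions (all in local calendar time):

* Detection period (DP): days from first to last detection, inclusive.
* Detection rate (DR): percent of DP days with at least one detection.
* Residency index (RI): per-habitat share of the fish's detection
  record, in percent.  Default mode ``detection_share`` divides raw
  detection counts (the published per-fish table contains sub-day
  resolution values like 0.06%, impossible under whole-day ratios);
  ``day_share`` apportions whole detection days, splitting days spent in
  several habitats by within-day detection share.
* Behavioral classes: a fish with DR below the transient threshold (50%)
  is Transient; otherwise it is an AR- or NR-resident when its RI for
  that reef reaches the resident threshold (70%, the unique round
  threshold separating every published resident from every published
  no-preferred-habitat fish), else NPH (No Preferred Habitat).
* EOPH: excursions outside the preferred habitat — maximal runs of
  hourly bins whose detections all come from non-preferred receivers.
  For fish without a preferred habitat the capture location is the
  reference.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .config import HABITATS, StudyConfig
from .io import join_habitat, local_day, to_local

AR_RESIDENT = "AR"
NR_RESIDENT = "NR"
NPH = "NPH"
TRANSIENT = "T"


@dataclasses.dataclass
class FishSummary:
    """One row of the per-fish results table."""

    tag_id: str
    capture_location: str | None
    behavior_class: str
    preferred_habitat: str | None
    detection_period_days: int
    detection_rate: float
    residency_index: dict[str, float]
    excursions: int
    standard_length_cm: float | None = None
    weight_g: float | None = None
    release_date: dt.date | None = None


def detection_period(fish_detections: pd.DataFrame, utc_offset_hours: float = 2.0) -> int:
    """Inclusive day span between first and last detection."""
    if fish_detections.empty:
        raise ValueError("detection period undefined for a fish with no detections")
    days = local_day(fish_detections["timestamp"], utc_offset_hours)
    return int((days.max() - days.min()).days) + 1


def detection_rate(fish_detections: pd.DataFrame, utc_offset_hours: float = 2.0) -> float:
    """Percent of the detection period's days with >= 1 detection."""
    dp = detection_period(fish_detections, utc_offset_hours)
    days = local_day(fish_detections["timestamp"], utc_offset_hours)
    return 100.0 * days.nunique() / dp


def residency_index(
    fish_detections: pd.DataFrame,
    stations: pd.DataFrame | None = None,
    mode: str = "detection_share",
    utc_offset_hours: float = 2.0,
) -> dict[str, float]:
    """Per-habitat share (percent) of one fish's detection record.

    ``detection_share`` (default): share of raw detections per habitat.
    ``day_share``: share of detection days, a day split across habitats
    contributing fractionally by its within-day detection share.  Both
    sum to 100 whenever the fish has any detections.
    """
    if fish_detections.empty:
        raise ValueError("residency index undefined for a fish with no detections")
    if mode not in ("detection_share", "day_share"):
        raise ValueError(f"unknown mode {mode!r}")
    det = fish_detections
    if "habitat" not in det.columns:
        if stations is None:
            raise ValueError("need a station table to resolve habitats")
        det = join_habitat(det, stations)
    if mode == "detection_share":
        share = det["habitat"].value_counts(normalize=True) * 100.0
    else:
        day = local_day(det["timestamp"], utc_offset_hours)
        within = (
            det.groupby([day, det["habitat"]], observed=True)
            .size()
            .groupby(level=0)
            .transform(lambda s: s / s.sum())
        )
        share = within.groupby(level=1).sum()
        share = share / share.sum() * 100.0
    return {hab: float(share.get(hab, 0.0)) for hab in HABITATS}


def classify_behavior(
    dr: float, ri: dict[str, float], cfg: StudyConfig | None = None
) -> tuple[str, str | None]:
    """Assign the behavioral class and preferred habitat of one fish.

    Transient below the DR threshold; otherwise resident of the reef
    whose RI reaches the resident threshold (AR checked first, but the
    two cannot both exceed 70 of a 100-sum); else NPH.
    """
    cfg = cfg or StudyConfig()
    if dr < cfg.transient_dr_threshold:
        return TRANSIENT, None
    if ri.get("AR", 0.0) >= cfg.resident_ri_threshold:
        return AR_RESIDENT, "AR"
    if ri.get("NR", 0.0) >= cfg.resident_ri_threshold:
        return NR_RESIDENT, "NR"
    return NPH, None


def count_excursions(
    fish_detections: pd.DataFrame,
    preferred_habitat: str,
    stations: pd.DataFrame | None = None,
    utc_offset_hours: float = 2.0,
) -> tuple[int, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Count excursions outside the preferred (or reference) habitat.

    An excursion is a maximal run of hourly bins whose detections all
    come from non-preferred receivers, bounded by preferred-habitat
    detections or by the start/end of the record; hours with no
    detections at all do not split a run.  Returns the count and the
    (first bin start, last bin start) local-time interval of each
    excursion.
    """
    det = fish_detections
    if "habitat" not in det.columns:
        if stations is None:
            raise ValueError("need a station table to resolve habitats")
        det = join_habitat(det, stations)
    if det.empty:
        return 0, []
    hour_bin = to_local(det["timestamp"], utc_offset_hours).dt.floor("h")
    at_pref = (
        det.assign(bin=hour_bin)
        .groupby("bin", observed=True)["habitat"]
        .agg(lambda h: (h == preferred_habitat).any())
        .sort_index()
    )
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    run_start: pd.Timestamp | None = None
    prev_bin: pd.Timestamp | None = None
    for b, pref in at_pref.items():
        if not pref:
            if run_start is None:
                run_start = b
            prev_bin = b
        else:
            if run_start is not None:
                intervals.append((run_start, prev_bin))
                run_start = None
    if run_start is not None:
        intervals.append((run_start, prev_bin))
    return len(intervals), intervals


def summarize_fish(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    stations: pd.DataFrame,
    cfg: StudyConfig | None = None,
    ri_mode: str = "detection_share",
) -> pd.DataFrame:
    """Build the per-fish summary table (one row per detected fish).

    Fish with zero detections are omitted (their metrics are undefined).
    Columns follow the published table schema: capture location,
    movement group, size, weight, release date, DP, DR, RI per habitat
    and EOPH.
    """
    cfg = cfg or StudyConfig()
    det = join_habitat(detections, stations)
    fish = tags[tags["kind"] == "fish"]
    by_tag = dict(iter(det.groupby("tag_id", observed=True)))
    rows = []
    for _, tag in fish.iterrows():
        fdet = by_tag.get(tag["tag_id"])
        if fdet is None or fdet.empty:
            continue
        dp = detection_period(fdet, cfg.utc_offset_hours)
        dr = detection_rate(fdet, cfg.utc_offset_hours)
        ri = residency_index(fdet, mode=ri_mode, utc_offset_hours=cfg.utc_offset_hours)
        group, preferred = classify_behavior(dr, ri, cfg)
        reference = preferred if preferred is not None else tag["capture_location"]
        eoph, _ = count_excursions(
            fdet, reference, utc_offset_hours=cfg.utc_offset_hours
        )
        rows.append(
            {
                "fish_id": tag["tag_id"],
                "capture_location": tag["capture_location"],
                "movement_group": group,
                "preferred_habitat": preferred,
                "standard_length_cm": tag.get("standard_length_cm"),
                "weight_g": tag.get("weight_g"),
                "release_date": pd.Timestamp(tag["release_datetime"]).date(),
                "dp_days": dp,
                "dr": dr,
                "ri_nr": ri["NR"],
                "ri_ar": ri["AR"],
                "ri_sw": ri["SW"],
                "ri_cv": ri["CV"],
                "eoph": eoph,
            }
        )
    return pd.DataFrame(rows)


def classify_table(
    summaries: pd.DataFrame, cfg: StudyConfig | None = None
) -> pd.Series:
    """Apply the classification rule to a summary table's DR/RI columns.

    Expects columns ``dr``, ``ri_nr``, ``ri_ar``, ``ri_sw``, ``ri_cv``;
    returns the movement-group label per row.
    """
    cfg = cfg or StudyConfig()
    labels = []
    for _, row in summaries.iterrows():
        ri = {
            "NR": row["ri_nr"],
            "AR": row["ri_ar"],
            "SW": row["ri_sw"],
            "CV": row["ri_cv"],
        }
        labels.append(classify_behavior(row["dr"], ri, cfg)[0])
    return pd.Series(labels, index=summaries.index, name="movement_group")


def connectivity_summary(
    summaries: pd.DataFrame,
    detections: pd.DataFrame | None = None,
    stations: pd.DataFrame | None = None,
    utc_offset_hours: float = 2.0,
) -> dict:
    """Seascape-connectivity aggregates from the per-fish summary table.

    Returns per-habitat counts of fish detected there at least once
    (nonzero RI share), the excursion-count histogram of resident fish,
    and — when detection records are supplied — the months in which
    seawall and distant-coast (CV) visits occurred.
    """
    ri_cols = {"NR": "ri_nr", "AR": "ri_ar", "SW": "ri_sw", "CV": "ri_cv"}
    visited = {hab: int((summaries[col] > 0).sum()) for hab, col in ri_cols.items()}
    residents = summaries[summaries["movement_group"].isin([AR_RESIDENT, NR_RESIDENT])]
    histogram = (
        residents["eoph"].value_counts().sort_index().to_dict()
        if not residents.empty
        else {}
    )
    out = {
        "n_fish": int(len(summaries)),
        "visited_fish_per_habitat": visited,
        "n_residents": int(len(residents)),
        "resident_excursion_histogram": {int(k): int(v) for k, v in histogram.items()},
        "residents_without_excursions": int((residents["eoph"] == 0).sum())
        if not residents.empty
        else 0,
    }
    if detections is not None and stations is not None:
        det = join_habitat(detections, stations)
        det = det[det["tag_id"].isin(summaries["fish_id"])]
        months: dict[str, list[int]] = {}
        for hab in ("SW", "CV"):
            sub = det[det["habitat"] == hab]
            months[hab] = sorted(
                to_local(sub["timestamp"], utc_offset_hours).dt.month.unique().tolist()
            )
        out["visit_months"] = months
    return out
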