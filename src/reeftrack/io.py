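"""Readers, writers and the in-memory data model.

Collections of records are held as pandas DataFrames with fixed column
contracts (the natural container for receiver-log analysis):

* detections: ``timestamp`` (datetime64, UTC), ``receiver_id``, ``tag_id``
* stations:   ``receiver_id``, ``habitat``, ``zone_label``, ``latitude``,
  ``longitude``, ``depth_m``, ``detection_range_m``
* tags:       ``tag_id``, ``kind`` (fish/control), ``release_datetime``,
  ``capture_location``, ``standard_length_cm``, ``weight_g``,
  ``ping_interval_s``, ``ping_interval_min_s``, ``ping_interval_max_s``

Timestamps are stored UTC internally; all hour-of-day and calendar-day
computations apply the configurable fixed local offset from
:class:`~reeftrack.config.StudyConfig` (diel phases are meaningless in
UTC).  Single-record views are available as lightweight dataclasses.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HABITATS, StudyConfig

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["timestamp", "receiver_id", "tag_id"]

STATION_COLUMNS = [
    "receiver_id",
    "habitat",
    "zone_label",
    "latitude",
    "longitude",
    "depth_m",
    "detection_range_m",
]

TAG_COLUMNS = [
    "tag_id",
    "kind",
    "release_datetime",
    "capture_location",
    "standard_length_cm",
    "weight_g",
    "ping_interval_s",
    "ping_interval_min_s",
    "ping_interval_max_s",
]


@dataclasses.dataclass(frozen=True)
class DetectionRecord:
    """One received ping: when, where (receiver) and who (transmitter)."""

    timestamp: dt.datetime
    receiver_id: str
    tag_id: str


@dataclasses.dataclass(frozen=True)
class ReceiverStation:
    receiver_id: str
    habitat: str
    zone_label: str
    latitude: float
    longitude: float
    depth_m: float
    detection_range_m: float

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.detection_range_m <= 0:
            raise ValueError("detection_range_m must be > 0")


@dataclasses.dataclass(frozen=True)
class TransmitterRecord:
    tag_id: str
    kind: str  # "fish" or "control"
    release_datetime: dt.datetime
    capture_location: str | None = None
    standard_length_cm: float | None = None
    weight_g: float | None = None
    ping_interval_s: float = 60.0
    ping_interval_min_s: float = 45.0
    ping_interval_max_s: float = 95.0

    def __post_init__(self) -> None:
        if self.kind not in ("fish", "control"):
            raise ValueError(f"kind must be fish|control, got {self.kind!r}")


class MalformedRowError(ValueError):
    """A CSV row could not be parsed; carries the 1-based line number."""


# ---------------------------------------------------------------------------
# local-time helpers

def to_local(timestamps: pd.Series, utc_offset_hours: float) -> pd.Series:
    """Shift UTC timestamps to the study's fixed local offset."""
    return timestamps + pd.Timedelta(hours=utc_offset_hours)


def local_day(timestamps: pd.Series, utc_offset_hours: float) -> pd.Series:
    """Local calendar day of each UTC timestamp."""
    return to_local(timestamps, utc_offset_hours).dt.normalize()


def local_hour(timestamps: pd.Series, utc_offset_hours: float) -> pd.Series:
    """Local hour-of-day bin (half-open [h, h+1)) of each UTC timestamp."""
    return to_local(timestamps, utc_offset_hours).dt.hour


# ---------------------------------------------------------------------------
# readers

def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"receiver_id": str, "zone_label": str})
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stations file missing columns: {sorted(missing)}")
    bad = ~df["habitat"].isin(HABITATS)
    if bad.any():
        raise ValueError(
            f"unknown habitat values: {sorted(df.loc[bad, 'habitat'].unique())}"
        )
    if (df["detection_range_m"] <= 0).any():
        raise ValueError("detection_range_m must be > 0 for every station")
    if df["receiver_id"].duplicated().any():
        raise ValueError("duplicate receiver_id in stations file")
    return df[STATION_COLUMNS]


def read_tags(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    missing = set(TAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tags file missing columns: {sorted(missing)}")
    df["release_datetime"] = pd.to_datetime(df["release_datetime"])
    bad = ~df["kind"].isin(["fish", "control"])
    if bad.any():
        raise ValueError("tag kind must be 'fish' or 'control'")
    if df["tag_id"].duplicated().any():
        raise ValueError("duplicate tag_id in tags file")
    return df[TAG_COLUMNS]


def read_detections(
    path: str | Path,
    stations: pd.DataFrame | None = None,
    tags: pd.DataFrame | None = None,
    *,
    on_unknown: str = "quarantine",
    quarantine_path: str | Path | None = None,
    timestamp_format: str | None = None,
) -> pd.DataFrame:
    """Read a receiver detection log (CSV export shape).

    Rows whose receiver or tag id does not resolve against the station/tag
    tables are either rejected (``on_unknown='error'``) or removed with a
    warning and optionally written to ``quarantine_path``
    (``on_unknown='quarantine'``).  Malformed timestamps raise
    :class:`MalformedRowError` with the offending line number.
    Returns records sorted by timestamp.
    """
    if on_unknown not in ("quarantine", "error"):
        raise ValueError("on_unknown must be 'quarantine' or 'error'")
    df = pd.read_csv(path, dtype={"receiver_id": str, "tag_id": str})
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections file missing columns: {sorted(missing)}")
    parsed = pd.to_datetime(df["timestamp"], format=timestamp_format, errors="coerce")
    if parsed.isna().any():
        # +2: header line and 1-based numbering
        line = int(parsed.index[parsed.isna()][0]) + 2
        raise MalformedRowError(f"unparseable timestamp at line {line} of {path}")
    df["timestamp"] = parsed

    unknown = pd.Series(False, index=df.index)
    if stations is not None:
        unknown |= ~df["receiver_id"].isin(stations["receiver_id"])
    if tags is not None:
        unknown |= ~df["tag_id"].isin(tags["tag_id"])
    if unknown.any():
        if on_unknown == "error":
            raise ValueError(f"{int(unknown.sum())} records with unknown ids in {path}")
        warnings.warn(
            f"quarantined {int(unknown.sum())} records with unknown ids",
            stacklevel=2,
        )
        if quarantine_path is not None:
            write_detections(df[unknown], quarantine_path)
        df = df[~unknown]
    return (
        df[DETECTION_COLUMNS]
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    out = detections[DETECTION_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_stations(stations: pd.DataFrame, path: str | Path) -> None:
    stations[STATION_COLUMNS].to_csv(path, index=False)


def write_tags(tags: pd.DataFrame, path: str | Path) -> None:
    out = tags[TAG_COLUMNS].copy()
    out["release_datetime"] = pd.to_datetime(out["release_datetime"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fish summary table (the per-fish results table schema)

SUMMARY_COLUMNS = [
    "fish_id",
    "capture_location",
    "movement_group",
    "standard_length_cm",
    "weight_g",
    "release_date",
    "dp_days",
    "dr",
    "ri_nr",
    "ri_ar",
    "ri_sw",
    "ri_cv",
    "eoph",
]


def write_fish_summary(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write the per-fish summary table (one row per fish).

    DR and RI columns are formatted to 2 decimals, matching the published
    table convention.
    """
    out = summaries.reindex(columns=SUMMARY_COLUMNS).copy()
    for col in ("dr", "ri_nr", "ri_ar", "ri_sw", "ri_cv"):
        out[col] = out[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
    out.to_csv(path, index=False)


def load_table2() -> pd.DataFrame:
    """Load the packaged 74-fish published summary table.

    A verbatim transcription of the per-individual capture, residency and
    movement-pattern table of the source study (74 white seabream retained
    after quality control), used as the desk-scale reference dataset.
    """
    with resources.files("reeftrack").joinpath("data/table2.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"capture_location": str, "movement_group": str})
    df["release_date"] = pd.to_datetime(df["release_date"]).dt.date
    return df


def join_habitat(detections: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Attach each detection's habitat via its receiver. Unknown ids raise."""
    merged = detections.merge(
        stations[["receiver_id", "habitat"]], on="receiver_id", how="left"
    )
    if merged["habitat"].isna().any():
        bad = merged.loc[merged["habitat"].isna(), "receiver_id"].unique()
        raise ValueError(f"receivers missing from station table: {sorted(bad)}")
    return merged


def validate_dataset(
    detections: pd.DataFrame,
    stations: pd.DataFrame,
    tags: pd.DataFrame,
) -> None:
    """Check that every record joins to exactly one station and transmitter."""
    if not detections["receiver_id"].isin(stations["receiver_id"]).all():
        raise ValueError("detections reference unknown receivers")
    if not detections["tag_id"].isin(tags["tag_id"]).all():
        raise ValueError("detections reference unknown transmitters")
    if not stations["receiver_id"].is_unique:
        raise ValueError("duplicate receiver_id in stations")
    if not tags["tag_id"].is_unique:
        raise ValueError("duplicate tag_id in tags")
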