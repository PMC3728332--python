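"""Sentinel-tag correction of detection counts, and area standardization.

Detection probability of acoustic receivers varies with environmental
conditions (sea state, biological noise, thermoclines), with marked dips
around dawn and dusk.  Fixed-position control (sentinel) transmitters
emit at a known interval, so the fraction of their pings that is actually
received estimates the detection probability p of that habitat's
receivers.  Fish counts are rescaled by a corrective coefficient derived
from p, computed per habitat, ISO week and hour-of-day (weekly rather
than study-wide, since conditions drift seasonally).

The coefficient is normalized within each week,

    c(w, h) = p_bar(w) / max(p(w, h), p_floor),

where ``p_bar(w)`` is the mean of the non-missing hourly probabilities of
that week.  Uniform detection probability therefore yields c = 1 (the
correction is a no-op) and corrected counts stay on the raw-count scale.
Cells without control data get c = 1.  Habitats without control tags
(seawalls, distant coast) are left uncorrected.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import join_habitat, local_day, local_hour

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["tag_id", "date", "hour", "habitat", "n"]


def hourly_counts(
    detections: pd.DataFrame,
    stations: pd.DataFrame | None = None,
    utc_offset_hours: float = 2.0,
) -> pd.DataFrame:
    """Detections per (tag, local day, hour[, habitat]).

    Hour bins are half-open [h, h+1) in local time.  Days with no
    detections are absent (structural zeros are reinstated where needed,
    e.g. when assembling model cells or hourly profiles).
    """
    if detections.empty:
        cols = COUNT_COLUMNS if stations is not None else [
            c for c in COUNT_COLUMNS if c != "habitat"
        ]
        return pd.DataFrame(columns=cols)
    df = detections.copy()
    if stations is not None:
        df = join_habitat(df, stations)
    df["date"] = local_day(df["timestamp"], utc_offset_hours)
    df["hour"] = local_hour(df["timestamp"], utc_offset_hours)
    keys = ["tag_id", "date", "hour"] + (["habitat"] if stations is not None else [])
    out = df.groupby(keys, observed=True).size().rename("n").reset_index()
    return out


def _iso_week_key(dates: pd.Series) -> pd.Series:
    iso = pd.to_datetime(dates).dt.isocalendar()
    return iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)


def control_detection_probability(
    control_detections: pd.DataFrame,
    tags: pd.DataFrame,
    stations: pd.DataFrame,
    utc_offset_hours: float = 2.0,
) -> pd.DataFrame:
    """Estimate p(habitat, week, hour) from control-tag detections.

    For each control tag, the detections received in hour-of-day h summed
    over the days of ISO week w are divided by the expected number of
    emitted pings (3600 / nominal interval per hour, times the number of
    days of that week within the tag's active span).  Tags of the same
    habitat are averaged with equal weight; the result is clipped to
    [0, 1].  Habitat-weeks with no active control tag are absent from the
    output (missing cells).

    Returns a DataFrame with columns habitat, week, hour, p.
    """
    controls = tags[tags["kind"] == "control"]
    det = control_detections[
        control_detections["tag_id"].isin(controls["tag_id"])
    ]
    if det.empty:
        return pd.DataFrame(columns=["habitat", "week", "hour", "p"])
    counts = hourly_counts(det, stations, utc_offset_hours)
    counts["week"] = _iso_week_key(counts["date"])

    rows = []
    for tag_id, tag_counts in counts.groupby("tag_id"):
        interval = float(
            controls.loc[controls["tag_id"] == tag_id, "ping_interval_s"].iloc[0]
        )
        expected_per_hour = 3600.0 / interval
        habitat = tag_counts["habitat"].mode().iloc[0]  # fixed position
        # active span: first to last day heard
        d0, d1 = tag_counts["date"].min(), tag_counts["date"].max()
        span = pd.date_range(d0, d1, freq="D")
        active = pd.DataFrame({"date": span, "week": _iso_week_key(pd.Series(span))})
        days_per_week = active.groupby("week").size()
        obs = (
            tag_counts.groupby(["week", "hour"])["n"].sum().rename("obs").reset_index()
        )
        full = pd.MultiIndex.from_product(
            [days_per_week.index, range(24)], names=["week", "hour"]
        )
        obs = obs.set_index(["week", "hour"]).reindex(full, fill_value=0).reset_index()
        obs["p"] = obs.apply(
            lambda r: r["obs"] / (expected_per_hour * days_per_week[r["week"]]),
            axis=1,
        ).clip(0.0, 1.0)
        obs["habitat"] = habitat
        obs["tag_id"] = tag_id
        rows.append(obs[["habitat", "week", "hour", "tag_id", "p"]])
    per_tag = pd.concat(rows, ignore_index=True)
    out = (
        per_tag.groupby(["habitat", "week", "hour"])["p"]
        .mean()
        .reset_index()
        .sort_values(["habitat", "week", "hour"])
        .reset_index(drop=True)
    )
    return out


def correction_coefficients(
    p_table: pd.DataFrame, p_floor: float = 0.05
) -> pd.DataFrame:
    """Fill the corrective coefficient c = p_bar(w) / max(p, p_floor).

    ``p_bar(w)`` is the mean of non-missing p over the 24 hours of each
    (habitat, week).  Rows with missing p get c = 1.  Floor breaches are
    logged.
    """
    table = p_table.copy()
    if table.empty:
        table["c"] = pd.Series(dtype=float)
        return table
    n_floored = int((table["p"].dropna() < p_floor).sum())
    if n_floored:
        logger.warning(
            "%d control probability cells below floor %.3g", n_floored, p_floor
        )
    pbar = table.groupby(["habitat", "week"])["p"].transform("mean")
    table["c"] = pbar / np.maximum(table["p"], p_floor)
    table.loc[table["p"].isna(), "c"] = 1.0
    return table


def apply_correction(
    fish_counts: pd.DataFrame,
    correction_table: pd.DataFrame,
) -> pd.DataFrame:
    """Rescale per-(tag, day, hour, habitat) counts by c(habitat, week, hour).

    Cells with no matching correction entry keep their raw value (c = 1)
    with a warning; habitats absent from the table (no control tags
    there) are silently uncorrected.  Output counts are real-valued.
    """
    out = fish_counts.copy()
    if out.empty:
        out["n_corrected"] = pd.Series(dtype=float)
        return out
    out["week"] = _iso_week_key(out["date"])
    merged = out.merge(
        correction_table[["habitat", "week", "hour", "c"]],
        on=["habitat", "week", "hour"],
        how="left",
    )
    corrected_habitats = set(correction_table["habitat"].unique())
    unmatched = merged["c"].isna() & merged["habitat"].isin(corrected_habitats)
    if unmatched.any():
        warnings.warn(
            f"{int(unmatched.sum())} count cells had no correction entry; "
            "left uncorrected (c = 1)",
            stacklevel=2,
        )
    merged["c"] = merged["c"].fillna(1.0)
    merged["n_corrected"] = merged["n"] * merged["c"]
    return merged.drop(columns=["week"])


def standardize_by_area(
    habitat_counts: pd.DataFrame,
    cfg: StudyConfig,
    value_col: str = "n",
) -> pd.DataFrame:
    """Convert per-habitat counts to detections per km^2.

    Every habitat present in the data must have a configured sampling
    area.
    """
    out = habitat_counts.copy()
    missing = set(out["habitat"].unique()) - set(cfg.habitat_area)
    if missing:
        raise ValueError(f"no sampling area configured for habitats {sorted(missing)}")
    areas = out["habitat"].map(cfg.habitat_area)
    out[value_col + "_per_km2"] = out[value_col] / areas
    return out


class SentinelCorrector:
    """Fit a weekly x hourly correction table from control-tag detections
    and apply it to fish count matrices.

    Thin stateful wrapper over :func:`control_detection_probability`,
    :func:`correction_coefficients` and :func:`apply_correction`.
    """

    def __init__(self, p_floor: float = 0.05, utc_offset_hours: float = 2.0):
        self.p_floor = p_floor
        self.utc_offset_hours = utc_offset_hours
        self.table_: pd.DataFrame | None = None

    def fit(
        self,
        control_detections: pd.DataFrame,
        tags: pd.DataFrame,
        stations: pd.DataFrame,
    ) -> "SentinelCorrector":
        p = control_detection_probability(
            control_detections, tags, stations, self.utc_offset_hours
        )
        self.table_ = correction_coefficients(p, self.p_floor)
        return self

    def transform(self, fish_counts: pd.DataFrame) -> pd.DataFrame:
        if self.table_ is None:
            raise RuntimeError("SentinelCorrector is not fitted")
        return apply_correction(fish_counts, self.table_)
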