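"""Diel-pattern analysis: phase assignment, hourly profiles, the Poisson
mixed model of diel effects, and the supporting univariate tests.

The diel phase (day vs night) of each timestamp is delimited by computed
local sunrise and sunset (day iff sunrise <= t < sunset).  Hourly
profiles are the mean and standard error of detections per hour-of-day
over (tag, day) cells, optionally area-standardized (per km^2) and/or
sentinel-corrected.  The formal test is a Poisson GLMM on per
(tag, day, hour) counts with fixed effects diel phase, fish size (cm,
uncentered) and their interaction, and crossed random intercepts for day
and transmitter (see :mod:`reeftrack.glmm`).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import scipy.stats

from .config import StudyConfig
from .glmm import PoissonGLMMResult, fit_poisson_glmm
from .solar import SolarEvents, sun_times


def solar_events_for_dates(
    dates: list[dt.date] | pd.Series, cfg: StudyConfig
) -> dict[dt.date, SolarEvents]:
    return {
        d: sun_times(d, cfg.study_latitude, cfg.study_longitude)
        for d in pd.Series(list(dates)).unique()
    }


def assign_diel_phase(
    timestamps: pd.Series, cfg: StudyConfig | None = None
) -> pd.Series:
    """Label each UTC timestamp ``day`` or ``night``.

    Day is the half-open interval [sunrise, sunset) of the timestamp's
    local calendar date at the study coordinates.
    """
    cfg = cfg or StudyConfig()
    ts = pd.to_datetime(timestamps)
    local_dates = (ts + pd.Timedelta(hours=cfg.utc_offset_hours)).dt.date
    events = solar_events_for_dates(local_dates, cfg)
    out = []
    for t, d in zip(ts, local_dates):
        ev = events[d]
        out.append("day" if ev.sunrise_utc <= t.to_pydatetime() < ev.sunset_utc else "night")
    return pd.Series(out, index=timestamps.index, name="diel_phase")


def hourly_phase_table(dates: list[dt.date], cfg: StudyConfig) -> pd.DataFrame:
    """Diel phase of each (local date, hour) cell, judged at the bin
    midpoint.  Used when assigning phases to hourly count cells."""
    rows = []
    for d in pd.Series(list(dates)).unique():
        ev = sun_times(d, cfg.study_latitude, cfg.study_longitude)
        for h in range(24):
            mid_local = dt.datetime.combine(d, dt.time(h, 30))
            mid_utc = mid_local - dt.timedelta(hours=cfg.utc_offset_hours)
            rows.append(
                {
                    "date": pd.Timestamp(d),
                    "hour": h,
                    "diel_phase": "day"
                    if ev.sunrise_utc <= mid_utc < ev.sunset_utc
                    else "night",
                }
            )
    return pd.DataFrame(rows)


def _full_hour_grid(counts: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Reinstate structural zeros: every (tag, date) pair present in the
    count matrix contributes all 24 hour bins."""
    pairs = counts[["tag_id", "date"]].drop_duplicates()
    grid = pairs.merge(pd.DataFrame({"hour": range(24)}), how="cross")
    keys = ["tag_id", "date", "hour"]
    cell = counts.groupby(keys, observed=True)[value_col].sum().reset_index()
    return grid.merge(cell, on=keys, how="left").fillna({value_col: 0.0})


def hourly_profile(
    counts: pd.DataFrame,
    cfg: StudyConfig | None = None,
    value_col: str = "n",
    standardize: bool = False,
    habitat: str | None = None,
) -> pd.DataFrame:
    """Mean detections (+/- SE) per hour-of-day over (tag, day) cells.

    ``counts`` is an hourly count matrix (raw ``n`` or corrected
    ``n_corrected``).  With ``standardize`` the means are divided by the
    sampling area of ``habitat`` (detections per km^2).  Hours with no
    detections on a monitored (tag, day) enter as zeros.
    """
    cfg = cfg or StudyConfig()
    if counts.empty:
        return pd.DataFrame({"hour": range(24), "mean": 0.0, "se": 0.0})
    grid = _full_hour_grid(counts, value_col)
    prof = (
        grid.groupby("hour")[value_col]
        .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0)
        .reset_index()
    )
    prof["se"] = prof["se"].fillna(0.0)
    if standardize:
        if habitat is None:
            raise ValueError("standardize=True requires a habitat")
        if habitat not in cfg.habitat_area:
            raise ValueError(f"no sampling area configured for {habitat!r}")
        area = cfg.habitat_area[habitat]
        prof["mean"] /= area
        prof["se"] /= area
    return prof


def assemble_glmm_cells(
    counts: pd.DataFrame,
    tags: pd.DataFrame,
    cfg: StudyConfig | None = None,
    value_col: str = "n",
) -> pd.DataFrame:
    """Build the per-(tag, day, hour) modeling table.

    Counts are expanded to the full 24-hour grid of each monitored
    (tag, day); each cell gets its diel phase (bin midpoint vs computed
    sunrise/sunset) and, for fish, the tag's standard length.  Corrected
    real-valued counts are rounded to the nearest integer for the
    Poisson response.
    """
    cfg = cfg or StudyConfig()
    grid = _full_hour_grid(counts, value_col)
    phases = hourly_phase_table(
        pd.to_datetime(grid["date"]).dt.date.unique().tolist(), cfg
    )
    grid["date"] = pd.to_datetime(grid["date"])
    cells = grid.merge(phases, on=["date", "hour"], how="left")
    cells["is_day"] = (cells["diel_phase"] == "day").astype(float)
    size = tags.set_index("tag_id")["standard_length_cm"]
    cells["size_cm"] = cells["tag_id"].map(size)
    cells["count"] = np.rint(cells[value_col]).astype(int)
    cells["day_key"] = cells["date"].dt.strftime("%Y-%m-%d")
    return cells


def fit_diel_glmm(
    cells: pd.DataFrame,
    include_size: bool = True,
    fix_vc_sd: dict[str, float] | None = None,
) -> PoissonGLMMResult:
    """Poisson GLMM of hourly counts on diel phase (and fish size).

    Fixed effects: diel phase (day = 1), size in cm and their
    interaction (size terms omitted for control tags); crossed random
    intercepts for calendar day and transmitter, Laplace approximation.
    """
    data = cells.copy()
    fixed = ["is_day"]
    if include_size:
        if data["size_cm"].isna().any():
            raise ValueError("size covariate missing for some tags")
        data["day_x_size"] = data["is_day"] * data["size_cm"]
        fixed += ["size_cm", "day_x_size"]
    groups = ["day_key", "tag_id"]
    mapping = {"day_key": "day", "tag_id": "transmitter"}
    res = fit_poisson_glmm(data, "count", fixed, groups, fix_vc_sd=fix_vc_sd)
    res.vc_sd = {mapping.get(k, k): v for k, v in res.vc_sd.items()}
    res.n_groups = {mapping.get(k, k): v for k, v in res.n_groups.items()}
    res.params.index = [
        {"is_day": "diel_phase(day)", "size_cm": "size", "day_x_size": "diel_phase(day):size"}.get(i, i)
        for i in res.params.index
    ]
    return res


def pearson_hourly_correlation(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between two 24-bin hourly profiles.

    Returns (r, two-sided p) over the hourly means.
    """
    a = profile_a.sort_values("hour")["mean"].to_numpy()
    b = profile_b.sort_values("hour")["mean"].to_numpy()
    if len(a) != 24 or len(b) != 24:
        raise ValueError("hourly profiles must have 24 bins")
    r, p = scipy.stats.pearsonr(a, b)
    return float(r), float(p)


def anova_size_by_group(summaries: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of standard length across behavioral groups.

    Guards against a size sampling bias masquerading as a diel effect.
    Requires >= 2 groups with data.
    """
    groups = [
        g["standard_length_cm"].dropna().to_numpy()
        for _, g in summaries.groupby("movement_group")
    ]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two behavioral groups for the ANOVA")
    f, p = scipy.stats.f_oneway(*groups)
    return float(f), float(p)
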