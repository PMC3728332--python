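"""Sentinel correction: probability estimation, coefficients, application."""

import numpy as np
import pandas as pd
import pytest

from reeftrack.config import StudyConfig
from reeftrack.correction import (
    SentinelCorrector,
    apply_correction,
    control_detection_probability,
    correction_coefficients,
    hourly_counts,
    standardize_by_area,
)
from reeftrack.synth import (
    SimulationParams,
    default_stations,
    simulate_detections,
    simulate_occupancy,
)

from .conftest import toy_detections, toy_stations, toy_tags


class TestHourlyCounts:
    def test_direct_binning(self):
        det = toy_detections(
            [
                ("2011-06-01 08:05:00", "R-AR", "A"),  # local 10:05
                ("2011-06-01 08:30:00", "R-AR", "A"),  # local 10:30
                ("2011-06-01 09:59:00", "R-AR", "A"),  # local 11:59
            ]
        )
        out = hourly_counts(det, toy_stations())
        got = dict(zip(out["hour"], out["n"]))
        assert got == {10: 2, 11: 1}

    def test_bin_edge_is_half_open(self):
        det = toy_detections([("2011-06-01 09:00:00", "R-AR", "A")])  # local 11:00:00
        out = hourly_counts(det, toy_stations())
        assert list(out["hour"]) == [11]

    def test_empty(self):
        out = hourly_counts(toy_detections([]), toy_stations())
        assert out.empty


def _uniform_control_week(p_hour: float, n_days: int = 7) -> pd.DataFrame:
    """Control detections with constant hourly probability p_hour: a
    540-s sentinel emits 6.667 pings/h; round(p * 6.667 * n_days) pings
    observed in every hour bin of every day."""
    rows = []
    per_hour = 3600.0 / 540.0
    for d in range(n_days):
        for h in range(24):
            k = int(round(p_hour * per_hour))
            for i in range(k):
                ts = pd.Timestamp(2011, 6, 6) + pd.Timedelta(days=d, hours=h, minutes=2 + 7 * i)
                rows.append((str(ts - pd.Timedelta(hours=2)), "R-AR", "C1"))  # to UTC
    return toy_detections(rows)


def test_control_probability_arithmetic():
    # 6 of 6.667 expected pings received -> p = 0.90
    det = _uniform_control_week(0.9)
    tags = toy_tags(("C1",), kind="control")
    p = control_detection_probability(det, tags, toy_stations())
    assert p["habitat"].eq("AR").all()
    np.testing.assert_allclose(p["p"], 6 / (3600 / 540), atol=1e-9)


def test_control_probability_clipped_at_one():
    det = _uniform_control_week(1.05)  # 7 observed > 6.667 expected
    tags = toy_tags(("C1",), kind="control")
    p = control_detection_probability(det, tags, toy_stations())
    assert (p["p"] <= 1.0).all()
    assert p["p"].max() == pytest.approx(1.0)


def test_no_control_detections_gives_empty_table():
    tags = toy_tags(("C1",), kind="control")
    p = control_detection_probability(toy_detections([]), tags, toy_stations())
    assert p.empty


class TestCoefficients:
    @staticmethod
    def _table(p_by_hour):
        return pd.DataFrame(
            {
                "habitat": "AR",
                "week": "2011-W23",
                "hour": range(24),
                "p": p_by_hour,
            }
        )

    def test_uniform_p_gives_identity(self):
        t = correction_coefficients(self._table([0.8] * 24))
        np.testing.assert_allclose(t["c"], 1.0)

    def test_day_night_split(self):
        p = [0.5] * 12 + [1.0] * 12  # pbar = 0.75
        t = correction_coefficients(self._table(p))
        np.testing.assert_allclose(t.loc[t["hour"] < 12, "c"], 1.5)
        np.testing.assert_allclose(t.loc[t["hour"] >= 12, "c"], 0.75)

    def test_floor_bounds_dead_bins(self):
        p = [0.0] + [0.8] * 23
        t = correction_coefficients(self._table(p), p_floor=0.05)
        pbar = np.mean(p)
        assert t.loc[0, "c"] == pytest.approx(pbar / 0.05)
        assert np.isfinite(t["c"]).all() and (t["c"] > 0).all()

    def test_missing_cells_get_unit_coefficient(self):
        tab = self._table([0.8] * 24)
        tab.loc[5, "p"] = np.nan
        t = correction_coefficients(tab)
        assert t.loc[5, "c"] == 1.0


def _counts_frame(n_by_hour, date="2011-06-06", habitat="AR"):
    return pd.DataFrame(
        {
            "tag_id": "F1",
            "date": pd.Timestamp(date),
            "hour": range(len(n_by_hour)),
            "habitat": habitat,
            "n": n_by_hour,
        }
    )


def test_apply_correction_definition():
    counts = _counts_frame([10])
    table = pd.DataFrame(
        {"habitat": ["AR"], "week": ["2011-W23"], "hour": [0], "p": [0.5], "c": [1.5]}
    )
    out = apply_correction(counts, table)
    assert out["n_corrected"].iloc[0] == pytest.approx(15.0)


def test_uncovered_habitat_left_uncorrected():
    counts = _counts_frame([10], habitat="SW")
    table = pd.DataFrame(
        {"habitat": ["AR"], "week": ["2011-W23"], "hour": [0], "p": [0.5], "c": [1.5]}
    )
    out = apply_correction(counts, table)
    assert out["n_corrected"].iloc[0] == pytest.approx(10.0)


def test_missing_cell_warns_and_keeps_raw():
    counts = _counts_frame([4, 6])
    table = pd.DataFrame(
        {"habitat": ["AR"], "week": ["2011-W23"], "hour": [0], "p": [0.5], "c": [2.0]}
    )
    with pytest.warns(UserWarning, match="no correction entry"):
        out = apply_correction(counts, table)
    assert list(out["n_corrected"]) == [8.0, 6.0]


def test_identity_under_uniform_probability_end_to_end():
    # constant within-week control probability => corrected == raw exactly
    det = _uniform_control_week(0.9)
    tags = pd.concat(
        [toy_tags(("C1",), kind="control"), toy_tags(("F1",))], ignore_index=True
    )
    corr = SentinelCorrector().fit(det, tags, toy_stations())
    fish_counts = _counts_frame([3, 7, 0, 11])
    out = corr.transform(fish_counts)
    np.testing.assert_allclose(out["n_corrected"], out["n"], rtol=0, atol=1e-12)


def test_standardize_by_area():
    counts = pd.DataFrame({"habitat": ["AR", "NR", "NR"], "n": [169, 75, 0]})
    out = standardize_by_area(counts, StudyConfig())
    np.testing.assert_allclose(out["n_per_km2"], [100.0, 100.0, 0.0])
    with pytest.raises(ValueError, match="no sampling area"):
        standardize_by_area(pd.DataFrame({"habitat": ["XX"], "n": [1]}), StudyConfig())


def test_correction_flattens_sinusoidal_detectability():
    """A fish with constant true activity observed through a sinusoidal
    detection-probability curve: correcting by sentinels must strictly
    reduce the variance of the hourly profile."""
    params = SimulationParams(
        n_fish={"AR_nocturnal": 2, "NR_diurnal": 0, "NPH": 0, "transient": 0},
        window_days=21,
        release_stagger_days=0,
        activity_amplitude=0.0,  # constant true activity
        activity_base=0.8,
        dip_depth=0.5,  # pronounced dawn/dusk structure in d(h)
        weekly_sd=0.0,
        resident_stay=1.0,
    )
    rng = np.random.default_rng(5)
    truth, tags = simulate_occupancy(params, rng)
    stations = default_stations()
    det = simulate_detections(truth, tags, params, rng, stations)
    controls = tags.loc[tags["kind"] == "control", "tag_id"]
    cdet = det[det["tag_id"].isin(controls)]
    fdet = det[~det["tag_id"].isin(controls)]
    counts = hourly_counts(fdet, stations)
    corr = SentinelCorrector().fit(cdet, tags, stations)
    out = corr.transform(counts)
    raw_profile = out.groupby("hour")["n"].mean()
    cor_profile = out.groupby("hour")["n_corrected"].mean()
    assert cor_profile.var() < raw_profile.var()
    # corrected totals stay on the raw scale (same order of magnitude)
    assert 0.5 < out["n_corrected"].sum() / out["n"].sum() < 2.0
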