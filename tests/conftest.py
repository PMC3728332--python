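"""Shared fixtures: small synthetic studies and the published fish table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reeftrack.config import StudyConfig
from reeftrack.io import load_table2
from reeftrack.synth import SimulationParams, make_paper_like_fixture


@pytest.fixture(scope="session")
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_table2()


def small_params(**overrides) -> SimulationParams:
    """A reduced study: fewer fish, shorter window — fast unit-test scale."""
    defaults = dict(
        n_fish={"AR_nocturnal": 3, "NR_diurnal": 3, "NPH": 2, "transient": 2},
        window_days=21,
        release_stagger_days=2,
        n_controls_per_reef=2,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def small_study() -> dict:
    """A 10-fish, 3-week synthetic study shared across read-only tests."""
    return make_paper_like_fixture(seed=42, params=small_params())


@pytest.fixture(scope="session")
def paper_scale_study() -> dict:
    """The full 74-fish, 5-month synthetic study (generated once)."""
    return make_paper_like_fixture(seed=7)


def toy_detections(rows: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Build a detection frame from (iso_timestamp, receiver, tag) tuples."""
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "receiver_id": [r[1] for r in rows],
            "tag_id": [r[2] for r in rows],
        }
    )


def toy_stations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "receiver_id": ["R-AR", "R-NR", "R-SW", "R-CV"],
            "habitat": ["AR", "NR", "SW", "CV"],
            "zone_label": ["Z1", "CL1", "SW1", "CV1"],
            "latitude": [42.77, 42.90, 42.86, 42.48],
            "longitude": [3.05, 3.05, 3.04, 3.13],
            "depth_m": [15.0, 5.0, 6.0, 10.0],
            "detection_range_m": [350.0, 250.0, 250.0, 250.0],
        }
    )


def toy_tags(tag_ids=("A",), kind="fish") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": list(tag_ids),
            "kind": kind,
            "release_datetime": pd.Timestamp("2011-06-01 08:00:00"),
            "capture_location": "AR",
            "standard_length_cm": 25.0,
            "weight_g": 500.0,
            "ping_interval_s": 60.0 if kind == "fish" else 540.0,
            "ping_interval_min_s": 45.0 if kind == "fish" else 510.0,
            "ping_interval_max_s": 95.0 if kind == "fish" else 570.0,
        }
    )
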