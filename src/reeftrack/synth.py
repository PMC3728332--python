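"""Synthetic acoustic-telemetry datasets with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: fish
move among habitat patches (artificial reef AR, natural reef NR, harbor
seawalls SW, distant rocky coast CV, or off-array "away") following
per-archetype hourly Markov chains; transmitters emit on a jittered ping
interval (uniform 45-95 s for fish, ~9 min for sentinels) until battery
exhaustion; each emitted ping is detected with probability
activity(archetype, hour) x d(habitat, week, hour), where d is an
environmental detection-probability curve with dawn/dusk dips and weekly
drift, and activity encodes the diel behavior (nocturnal archetypes are
less detectable by day — sheltering fish transmit poorly — and
vice versa).  Sentinels are fixed, always-on (activity = 1) probes of d.

Four behavioral archetypes mirror the observed group structure:
AR-resident nocturnal, NR-resident diurnal, no-preferred-habitat (NPH,
diurnal, switching between reefs) and transient (mostly off-array).
Thinning is Bernoulli per ping with no inter-tag collision modeling (the
single-daily-detection QC rule is the collision treatment downstream).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

ARCHETYPES = ("AR_nocturnal", "NR_diurnal", "NPH", "transient")

_HAB_CODES = {"AR": 0, "NR": 1, "SW": 2, "CV": 3, "away": 4}
_CODE_HABS = {v: k for k, v in _HAB_CODES.items()}


@dataclasses.dataclass
class SimulationParams:
    """Generator settings; defaults mirror the monitored study design."""

    n_fish: dict[str, int] = dataclasses.field(
        default_factory=lambda: {
            "AR_nocturnal": 20,
            "NR_diurnal": 33,
            "NPH": 6,
            "transient": 15,
        }
    )
    window_start: dt.date = dt.date(2011, 6, 1)
    window_days: int = 150
    release_stagger_days: int = 30
    fish_interval_s: tuple[float, float] = (45.0, 95.0)
    control_interval_s: float = 540.0
    control_interval_jitter_s: float = 30.0
    battery_life_days: int = 151
    n_controls_per_reef: int = 3
    utc_offset_hours: float = 2.0
    # diel activity: base + amplitude * cos(2 pi (h - peak_hour) / 24)
    activity_base: float = 0.7
    activity_amplitude: float = 0.25
    nocturnal_peak_hour: float = 2.0
    diurnal_peak_hour: float = 14.0
    # environmental detection-probability curve
    env_base: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"AR": 0.65, "NR": 0.60, "SW": 0.60, "CV": 0.60}
    )
    dawn_hour: float = 6.0
    dusk_hour: float = 20.5
    dip_depth: float = 0.35  # relative depth of dawn/dusk dips
    dip_width_h: float = 1.2
    nr_day_boost: float = 0.12  # relative day-time excess on the NR
    weekly_sd: float = 0.10  # lognormal weekly drift of d
    # Markov occupancy (per hour) self-transition probabilities
    resident_stay: float = 0.995
    resident_away_return: float = 0.30
    nph_stay: float = 0.98
    nph_switch: float = 0.012
    transient_stay_away: float = 0.99
    transient_stay_home: float = 0.90

    def validate(self) -> None:
        for k, v in self.n_fish.items():
            if k not in ARCHETYPES:
                raise ValueError(f"unknown archetype {k!r}")
            if v < 0:
                raise ValueError("fish counts must be >= 0")
        probs = [
            self.resident_stay,
            self.resident_away_return,
            self.nph_stay,
            self.transient_stay_away,
            self.transient_stay_home,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("transition probabilities must be in [0, 1]")
        if self.activity_base - self.activity_amplitude <= 0:
            raise ValueError("activity profile must stay positive")


def default_stations() -> pd.DataFrame:
    """A 17-receiver array: 6 AR zones, 6 NR points, 2 seawalls, 3 CV."""
    rows = []
    for i in range(6):
        rows.append(("Z%d" % (i + 1), "AR", "Z%d" % (i + 1),
                     42.77 + 0.008 * i, 3.05, 15.0 + 2 * i, 350.0))
    for i in range(6):
        rows.append(("CL%d" % (i + 1), "NR", "CL%d" % (i + 1),
                     42.90 + 0.004 * i, 3.05, 5.0 + 3 * i, 250.0))
    rows.append(("SW-BL", "SW", "SW-BL", 42.86, 3.04, 6.0, 250.0))
    rows.append(("SW-LB", "SW", "SW-LB", 42.79, 3.04, 6.0, 250.0))
    for i in range(3):
        rows.append(("CV%d" % (i + 1), "CV", "CV%d" % (i + 1),
                     42.48 + 0.01 * i, 3.13, 10.0, 250.0))
    return pd.DataFrame(
        rows,
        columns=[
            "receiver_id", "habitat", "zone_label",
            "latitude", "longitude", "depth_m", "detection_range_m",
        ],
    )


def _activity_profile(archetype: str, p: SimulationParams) -> np.ndarray:
    h = np.arange(24, dtype=float)
    if archetype == "AR_nocturnal":
        peak = p.nocturnal_peak_hour
    elif archetype in ("NR_diurnal", "NPH"):
        peak = p.diurnal_peak_hour
    else:  # transient: no marked diel preference
        return np.full(24, p.activity_base + p.activity_amplitude / 2)
    return p.activity_base + p.activity_amplitude * np.cos(
        2 * np.pi * (h - peak) / 24.0
    )


def environment_curve(
    params: SimulationParams, habitat: str, week_factor: float = 1.0
) -> np.ndarray:
    """Hourly detection probability d(h) for one habitat and week."""
    h = np.arange(24, dtype=float)
    dip = np.exp(-0.5 * ((h - params.dawn_hour) / params.dip_width_h) ** 2) + np.exp(
        -0.5 * ((h - params.dusk_hour) / params.dip_width_h) ** 2
    )
    d = params.env_base[habitat] * (1.0 - params.dip_depth * dip)
    if habitat == "NR":
        day = (h >= params.dawn_hour) & (h < params.dusk_hour)
        d = d * (1.0 + params.nr_day_boost * day)
    return np.clip(d * week_factor, 0.0, 1.0)


def _transition_matrix(archetype: str, home: str, p: SimulationParams) -> np.ndarray:
    """5x5 hourly transition matrix over (AR, NR, SW, CV, away)."""
    T = np.zeros((5, 5))
    hi = _HAB_CODES[home]
    other_reef = _HAB_CODES["NR" if home == "AR" else "AR"]
    away = _HAB_CODES["away"]
    sw, cv = _HAB_CODES["SW"], _HAB_CODES["CV"]
    if archetype in ("AR_nocturnal", "NR_diurnal"):
        leak = 1.0 - p.resident_stay
        T[hi, hi] = p.resident_stay
        T[hi, away] = leak * 0.70
        T[hi, sw] = leak * 0.15
        T[hi, cv] = leak * 0.15
        for s in (sw, cv, other_reef):
            T[s, s] = 0.5
            T[s, hi] = 0.4
            T[s, away] = 0.1
        T[away, away] = 1.0 - p.resident_away_return
        T[away, hi] = p.resident_away_return
    elif archetype == "NPH":
        for a, b in ((hi, other_reef), (other_reef, hi)):
            T[a, a] = p.nph_stay
            T[a, b] = p.nph_switch
            T[a, away] = 1.0 - p.nph_stay - p.nph_switch
        T[away, away] = 0.5
        T[away, hi] = 0.25
        T[away, other_reef] = 0.25
        for s in (sw, cv):
            T[s, hi] = 1.0
    else:  # transient
        T[away, away] = p.transient_stay_away
        rem = 1.0 - p.transient_stay_away
        T[away, hi] = rem * 0.70
        T[away, sw] = rem * 0.10
        T[away, cv] = rem * 0.20
        for s in (hi, other_reef, sw, cv):
            T[s, s] = p.transient_stay_home
            T[s, away] = 1.0 - p.transient_stay_home
    # normalize rows defensively
    T = T / T.sum(axis=1, keepdims=True)
    return T


@dataclasses.dataclass
class SimulatedTruth:
    """Ground truth: per-tag hourly occupancy, archetype and activity."""

    occupancy: dict[str, np.ndarray]  # tag_id -> habitat code per hour
    archetype: dict[str, str]
    activity: dict[str, np.ndarray]  # tag_id -> 24-h relative detectability
    release_hour: dict[str, int]  # offset into the window, hours
    n_hours: int

    def occupancy_habitat(self, tag_id: str) -> list[str]:
        return [_CODE_HABS[c] for c in self.occupancy[tag_id]]


def simulate_occupancy(
    params: SimulationParams, seed: int | np.random.Generator = 0
) -> tuple[SimulatedTruth, pd.DataFrame]:
    """Draw hourly habitat occupancy for every fish, plus the tag table.

    Returns the truth object and a tag table (fish + sentinels) in the
    standard schema.  Deterministic for a fixed seed.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hours = params.window_days * 24
    occupancy, archetype, activity, release_hour = {}, {}, {}, {}
    tag_rows = []
    fid = 0
    for arch in ARCHETYPES:
        for _ in range(params.n_fish.get(arch, 0)):
            fid += 1
            tag_id = f"F{fid:03d}"
            if arch == "AR_nocturnal":
                home = "AR"
            elif arch == "NR_diurnal":
                home = "NR"
            elif arch == "NPH":
                home = "AR"  # NPH fish were tagged on the ARs
            else:
                home = "AR" if rng.random() < 0.5 else "NR"
            T = _transition_matrix(arch, home, params)
            cum = T.cumsum(axis=1)
            start = _HAB_CODES[home] if arch != "transient" else _HAB_CODES["away"]
            rel_h = int(rng.integers(0, params.release_stagger_days * 24 + 1))
            path = np.empty(n_hours, dtype=np.int8)
            path[:rel_h] = _HAB_CODES["away"]
            state = start
            draws = rng.random(n_hours - rel_h)
            for i, u in enumerate(draws):
                state = int(np.searchsorted(cum[state], u, side="right"))
                path[rel_h + i] = state
            occupancy[tag_id] = path
            archetype[tag_id] = arch
            activity[tag_id] = _activity_profile(arch, params)
            release_hour[tag_id] = rel_h
            length = float(np.round(rng.uniform(17.0, 35.0), 1))
            weight = float(
                np.clip(np.round(0.033 * length**3 + rng.normal(0, 30)), 155, 1220)
            )
            release_dt = dt.datetime.combine(
                params.window_start, dt.time(0)
            ) + dt.timedelta(hours=rel_h - params.utc_offset_hours)
            tag_rows.append(
                {
                    "tag_id": tag_id,
                    "kind": "fish",
                    "release_datetime": release_dt,
                    "capture_location": home,
                    "standard_length_cm": length,
                    "weight_g": weight,
                    "ping_interval_s": sum(params.fish_interval_s) / 2,
                    "ping_interval_min_s": params.fish_interval_s[0],
                    "ping_interval_max_s": params.fish_interval_s[1],
                }
            )
    # sentinels: fixed position on each reef, active the whole window
    for hab in ("AR", "NR"):
        for i in range(params.n_controls_per_reef):
            tag_id = f"C{hab}{i + 1}"
            occupancy[tag_id] = np.full(n_hours, _HAB_CODES[hab], dtype=np.int8)
            archetype[tag_id] = "control"
            activity[tag_id] = np.ones(24)
            release_hour[tag_id] = 0
            tag_rows.append(
                {
                    "tag_id": tag_id,
                    "kind": "control",
                    "release_datetime": dt.datetime.combine(
                        params.window_start, dt.time(0)
                    )
                    - dt.timedelta(hours=params.utc_offset_hours),
                    "capture_location": hab,
                    "standard_length_cm": np.nan,
                    "weight_g": np.nan,
                    "ping_interval_s": params.control_interval_s,
                    "ping_interval_min_s": params.control_interval_s
                    - params.control_interval_jitter_s,
                    "ping_interval_max_s": params.control_interval_s
                    + params.control_interval_jitter_s,
                }
            )
    truth = SimulatedTruth(occupancy, archetype, activity, release_hour, n_hours)
    return truth, pd.DataFrame(tag_rows)


def weekly_factors(
    params: SimulationParams, rng: np.random.Generator
) -> dict[tuple[str, int], float]:
    """Lognormal weekly drift of the environmental curve, per habitat."""
    n_weeks = params.window_days // 7 + 2
    return {
        (hab, w): float(np.exp(rng.normal(0.0, params.weekly_sd)))
        for hab in ("AR", "NR", "SW", "CV")
        for w in range(n_weeks)
    }


def simulate_detections(
    truth: SimulatedTruth,
    tags: pd.DataFrame,
    params: SimulationParams,
    seed: int | np.random.Generator = 0,
    stations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Thin each tag's emitted pings into a detection log.

    Emission times follow a renewal process with uniformly jittered
    gaps, truncated by battery life and the study window.  A ping is
    detected with probability activity(tag, hour) x d(habitat, week,
    hour) when the tag occupies a receiver-covered habitat ("away"
    yields nothing); the receiving station is drawn uniformly among the
    habitat's receivers.  Returns a standard detection DataFrame sorted
    by timestamp (UTC).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stations = stations if stations is not None else default_stations()
    receivers_by_hab = {
        hab: sub["receiver_id"].to_numpy()
        for hab, sub in stations.groupby("habitat")
    }
    wf = weekly_factors(params, rng)
    # per habitat: d(h) for each week index
    n_weeks = params.window_days // 7 + 2
    d_tab = {
        hab: np.stack(
            [environment_curve(params, hab, wf[(hab, w)]) for w in range(n_weeks)]
        )
        for hab in ("AR", "NR", "SW", "CV")
    }
    window_start_local = dt.datetime.combine(params.window_start, dt.time(0))
    t0_utc = np.datetime64(window_start_local) - np.timedelta64(
        int(params.utc_offset_hours * 3600), "s"
    )
    horizon_s = truth.n_hours * 3600

    frames = []
    for _, tag in tags.iterrows():
        tag_id = tag["tag_id"]
        rel_s = truth.release_hour[tag_id] * 3600
        end_s = min(rel_s + params.battery_life_days * 86400, horizon_s)
        lo, hi = float(tag["ping_interval_min_s"]), float(tag["ping_interval_max_s"])
        n_max = int((end_s - rel_s) / lo) + 2
        gaps = rng.uniform(lo, hi, n_max)
        times = rel_s + np.cumsum(gaps)
        times = times[times < end_s]
        if times.size == 0:
            continue
        hour_idx = (times // 3600).astype(int)
        hod = hour_idx % 24
        week = np.minimum(hour_idx // (24 * 7), n_weeks - 1)
        occ = truth.occupancy[tag_id][hour_idx]
        act = truth.activity[tag_id]
        p = np.zeros(times.size)
        for hab, code in _HAB_CODES.items():
            if hab == "away":
                continue
            sel = occ == code
            if sel.any():
                p[sel] = act[hod[sel]] * d_tab[hab][week[sel], hod[sel]]
        detected = rng.random(times.size) < p
        if not detected.any():
            continue
        t_det = times[detected]
        occ_det = occ[detected]
        recv = np.empty(t_det.size, dtype=object)
        for hab, code in _HAB_CODES.items():
            if hab == "away":
                continue
            sel = occ_det == code
            if sel.any():
                pool = receivers_by_hab.get(hab)
                if pool is None or len(pool) == 0:
                    recv[sel] = None
                else:
                    recv[sel] = pool[rng.integers(0, len(pool), int(sel.sum()))]
        keep = recv != None  # noqa: E711
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": t0_utc + t_det[keep].astype("timedelta64[s]"),
                    "receiver_id": recv[keep].astype(str),
                    "tag_id": tag_id,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["timestamp", "receiver_id", "tag_id"])
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    return out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def make_paper_like_fixture(seed: int = 0, params: SimulationParams | None = None) -> dict:
    """Full study-scale input bundle with ground truth.

    74 fish in the observed archetype proportions (20 AR-nocturnal, 33
    NR-diurnal, 6 NPH, 15 transient), the 17-receiver array, 6 sentinel
    tags and a ~5-month window.  Deterministic for a fixed seed.
    Returns dict with ``detections``, ``stations``, ``tags``, ``truth``
    and ``params``.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    truth, tags = simulate_occupancy(params, rng)
    stations = default_stations()
    detections = simulate_detections(truth, tags, params, rng, stations)
    return {
        "detections": detections,
        "stations": stations,
        "tags": tags,
        "truth": truth,
        "params": params,
    }
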