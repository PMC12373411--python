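"""Seeded synthetic cohort generator.

Produces every data stream the downstream analysis consumes — inertial sensor
segments, weekly 14-item well-being questionnaires, daily nutrition logs and
paired pre/post Likert surveys — with the statistical structure the analysis
assumes, so the full pipeline is testable without any recorded data.

Ground truth (true movement-event times, true well-being group labels, latent
pre-discretization survey values) is emitted alongside the data so that
oracle-based tests can compare recovered quantities against what was simulated.

All generators are bit-reproducible: identical (config, seed, identifiers)
yield identical output.  Randomness is derived from ``config.seed`` through
:class:`numpy.random.SeedSequence` with fixed per-stream child keys, so the
streams for different participants, sessions and data kinds are independent
and stable under reordering of calls.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODERATE, SENSOR_SITES, WELL, CohortConfig
from .errors import ConfigurationError, InputError

# fixed child-stream keys (never reorder: determinism contract)
_STREAM_PARTICIPANTS = 0
_STREAM_IMU = 1
_STREAM_SURVEY = 2
_STREAM_MHCSF = 3
_STREAM_NUTRITION = 4

DEFAULT_STUDY_START = _dt.date(2024, 1, 1)


@dataclass
class SensorFrame:
    """One sensor's time-stamped tri-axial acceleration for one game segment.

    Angular velocities (gx, gy, gz) are optional; the kinematic metrics do not
    use them.  ``event_times`` carries the generator's ground-truth movement
    event onsets (seconds) when the frame is simulated.
    """

    participant_id: str
    session_week: int
    game: str
    sensor_site: str
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray | None = None
    gy: np.ndarray | None = None
    gz: np.ndarray | None = None
    event_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sensor_site not in SENSOR_SITES:
            raise ConfigurationError(
                f"unknown sensor_site {self.sensor_site!r}; expected one of {SENSOR_SITES}"
            )
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise InputError("timestamps and acceleration components must have equal length")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise InputError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if self.n < 2:
            return 0.0
        dt = (self.timestamps[-1] - self.timestamps[0]) / (self.n - 1)
        return float(self.n * dt)


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# cohort roster
# ---------------------------------------------------------------------------

def simulate_participants(config: CohortConfig) -> pd.DataFrame:
    """Roster of the cohort: arm allocation, true well-being group, body mass
    and whether the participant completed both surveys.

    Returns a DataFrame with columns ``participant_id, arm, group, weight_kg,
    completer``.
    """
    rng = _rng(config, _STREAM_PARTICIPANTS)
    n = config.n_participants
    width = max(2, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    arm_order = rng.permutation(n)
    arms = np.empty(n, dtype=object)
    for rank, idx in enumerate(arm_order):
        arms[idx] = config.arms[rank % len(config.arms)]

    n_well = int(round(n * config.well_fraction))
    group = np.array([MODERATE] * n, dtype=object)
    group[rng.permutation(n)[:n_well]] = WELL

    weight = np.clip(
        rng.normal(config.weight_mean_kg, config.weight_sd_kg, size=n), 40.0, 110.0
    )

    completer = np.zeros(n, dtype=bool)
    completer[rng.permutation(n)[: config.n_survey_completers]] = True

    return pd.DataFrame(
        {
            "participant_id": ids,
            "arm": arms,
            "group": group,
            "weight_kg": np.round(weight, 2),
            "completer": completer,
        }
    )


# ---------------------------------------------------------------------------
# inertial sensor streams
# ---------------------------------------------------------------------------

def _half_sine_bursts(
    t: np.ndarray, events: np.ndarray, amplitude: float, width: float
) -> np.ndarray:
    """Sum of half-sine acceleration pulses of ``width`` seconds at ``events``."""
    burst = np.zeros_like(t)
    if len(t) < 2:
        return burst
    dt = t[1] - t[0]
    for e in events:
        i0 = int(np.ceil(e / dt))
        i1 = min(int(np.floor((e + width) / dt)), len(t) - 1)
        if i1 < i0:
            continue
        phase = (t[i0 : i1 + 1] - e) / width
        burst[i0 : i1 + 1] += amplitude * np.sin(np.pi * phase)
    return burst


def simulate_imu_session(
    config: CohortConfig,
    participant_id: str,
    session_week: int,
    game: str,
    group: str | None = None,
) -> list[SensorFrame]:
    """Simulate one game segment for one participant: one frame per sensor.

    The movement events of the segment are shared across the five sensors
    (they record the same body in motion); each sensor adds its own baseline
    noise.  The vertical axis carries gravity plus the movement bursts, so the
    magnitude series has a quiet floor near 1 g punctuated by clear peaks.

    Per-week intensity scaling is applied multiplicatively to the whole
    signal, so maximum and RMS acceleration scale by exactly the configured
    group growth factor in expectation.
    """
    if not (1 <= session_week <= config.weeks):
        raise InputError(f"session_week must be in 1..{config.weeks}")
    if game not in config.games:
        raise InputError(f"unknown game {game!r}")
    if group is None:
        roster = simulate_participants(config)
        row = roster[roster["participant_id"] == participant_id]
        if row.empty:
            raise InputError(f"unknown participant {participant_id!r}")
        group = str(row["group"].iloc[0])

    p_key = _participant_key(config, participant_id)
    game_idx = list(config.games).index(game)
    rng = _rng(config, _STREAM_IMU, p_key, session_week, game_idx)

    n = config.samples_per_segment
    fs = config.sampling_hz
    t = np.arange(n) / fs
    duration = config.segment_duration_s

    n_events = rng.poisson(config.peak_rate_hz * duration)
    events = np.sort(rng.uniform(0.0, duration, size=n_events))
    burst = _half_sine_bursts(t, events, config.peak_amplitude, config.burst_width_s)
    scale = config.intensity_scale(group, session_week)

    frames = []
    for site in SENSOR_SITES:
        noise = rng.normal(0.0, config.baseline_noise_sd, size=(3, n))
        ax = noise[0]
        ay = noise[1]
        az = config.gravity_ms2 + burst + noise[2]
        frames.append(
            SensorFrame(
                participant_id=participant_id,
                session_week=session_week,
                game=game,
                sensor_site=site,
                timestamps=t,
                ax=scale * ax,
                ay=scale * ay,
                az=scale * az,
                event_times=events,
            )
        )
    return frames


def _participant_key(config: CohortConfig, participant_id: str) -> int:
    """Stable small integer key for a participant id (its 1-based index)."""
    digits = "".join(c for c in participant_id if c.isdigit())
    if not digits:
        raise InputError(f"participant_id {participant_id!r} has no numeric index")
    return int(digits)


def simulate_cohort_imu(
    config: CohortConfig, participants: pd.DataFrame | None = None
) -> tuple[list[SensorFrame], pd.DataFrame]:
    """All sensor frames for the whole cohort, plus the roster used."""
    roster = simulate_participants(config) if participants is None else participants
    frames: list[SensorFrame] = []
    for _, row in roster.iterrows():
        for week in range(1, config.weeks + 1):
            for game in config.games:
                frames.extend(
                    simulate_imu_session(
                        config, row["participant_id"], week, game, group=row["group"]
                    )
                )
    return frames, roster


def frames_to_dataframe(frames: list[SensorFrame]) -> pd.DataFrame:
    """Flatten sensor frames to the long sensor-CSV schema
    (participant_id, week, game, sensor_site, t, ax, ay, az[, gx, gy, gz])."""
    parts = []
    for f in frames:
        d = {
            "participant_id": f.participant_id,
            "week": f.session_week,
            "game": f.game,
            "sensor_site": f.sensor_site,
            "t": f.timestamps,
            "ax": f.ax,
            "ay": f.ay,
            "az": f.az,
        }
        if f.gx is not None:
            d.update({"gx": f.gx, "gy": f.gy, "gz": f.gz})
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)


def dataframe_to_frames(df: pd.DataFrame) -> list[SensorFrame]:
    """Rebuild :class:`SensorFrame` objects from the long sensor-CSV schema."""
    required = {"participant_id", "week", "game", "sensor_site", "t", "ax", "ay", "az"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"sensor table missing columns: {sorted(missing)}")
    has_gyro = {"gx", "gy", "gz"}.issubset(df.columns)
    frames = []
    keys = ["participant_id", "week", "game", "sensor_site"]
    for (pid, week, game, site), g in df.groupby(keys, sort=True):
        g = g.sort_values("t")
        frames.append(
            SensorFrame(
                participant_id=str(pid),
                session_week=int(week),
                game=str(game),
                sensor_site=str(site),
                timestamps=g["t"].to_numpy(float),
                ax=g["ax"].to_numpy(float),
                ay=g["ay"].to_numpy(float),
                az=g["az"].to_numpy(float),
                gx=g["gx"].to_numpy(float) if has_gyro else None,
                gy=g["gy"].to_numpy(float) if has_gyro else None,
                gz=g["gz"].to_numpy(float) if has_gyro else None,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# pre/post survey
# ---------------------------------------------------------------------------

def simulate_survey_prepost(
    config: CohortConfig, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Paired pre/post Likert responses for the survey completers.

    Each item's (pre, post) pair is drawn from a bivariate normal with the
    configured latent moments and within-subject correlation, then discretized
    (round half away from zero) and clipped to the item's scale.  Both the
    latent draws (``pre_raw``/``post_raw``) and the observed Likert values
    (``pre_value``/``post_value``) are returned; configured moments are
    latent-scale moments.
    """
    roster = simulate_participants(config) if participants is None else participants
    completers = roster.loc[roster["completer"], "participant_id"].tolist()
    rng = _rng(config, _STREAM_SURVEY)

    rows = []
    for item in config.survey_item_params:
        rho = item.paired_correlation
        z1 = rng.standard_normal(len(completers))
        z2 = rng.standard_normal(len(completers))
        pre = item.pre_mean + item.pre_sd * z1
        post = item.post_mean + item.post_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        pre_v = np.clip(_round_half_away(pre), item.scale_min, item.scale_max)
        post_v = np.clip(_round_half_away(post), item.scale_min, item.scale_max)
        for i, pid in enumerate(completers):
            rows.append(
                {
                    "participant_id": pid,
                    "item_id": item.item_id,
                    "pre_raw": pre[i],
                    "post_raw": post[i],
                    "pre_value": int(pre_v[i]),
                    "post_value": int(post_v[i]),
                }
            )
    return pd.DataFrame(rows)


def survey_to_long(survey: pd.DataFrame, value_col_prefix: str = "") -> pd.DataFrame:
    """Convert the wide pre/post table to the long CSV schema
    ``participant_id,item_id,phase,value`` (observed Likert values)."""
    pre = survey[["participant_id", "item_id", "pre_value"]].rename(
        columns={"pre_value": "value"}
    )
    pre["phase"] = "pre"
    post = survey[["participant_id", "item_id", "post_value"]].rename(
        columns={"post_value": "value"}
    )
    post["phase"] = "post"
    out = pd.concat([pre, post], ignore_index=True)
    return out[["participant_id", "item_id", "phase", "value"]]


# ---------------------------------------------------------------------------
# weekly 14-item well-being questionnaire
# ---------------------------------------------------------------------------

def _item_probs(profile, n_items: int = 14) -> np.ndarray:
    """Normalize a group profile to an (n_items, 6) probability matrix."""
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != 6:
            raise ConfigurationError("per-group profile must have 6 category probabilities")
        arr = np.tile(arr, (n_items, 1))
    if arr.shape != (n_items, 6):
        raise ConfigurationError(f"profile must be 6 probs or {n_items}x6, got {arr.shape}")
    sums = arr.sum(axis=1)
    if np.any(arr < 0) or np.any(np.abs(sums - 1.0) > 1e-9):
        raise ConfigurationError("profile rows must be probability vectors summing to 1")
    return arr


def simulate_mhcsf_weekly(
    config: CohortConfig, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One 14-item frequency-scale response (categories 0-5) per participant
    per week, drawn from the participant's group profile.  The true group
    label is carried in ``true_group`` for oracle tests."""
    roster = simulate_participants(config) if participants is None else participants
    rng = _rng(config, _STREAM_MHCSF)
    probs = {g: _item_probs(p) for g, p in config.mhcsf_profile.items()}

    rows = []
    for _, person in roster.iterrows():
        p = probs[person["group"]]
        for week in range(1, config.weeks + 1):
            row = {
                "participant_id": person["participant_id"],
                "week": week,
                "true_group": person["group"],
            }
            for item in range(14):
                row[f"item_{item + 1:02d}"] = int(rng.choice(6, p=p[item]))
            rows.append(row)
    cols = ["participant_id", "week"] + [f"item_{i:02d}" for i in range(1, 15)] + [
        "true_group"
    ]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# nutrition logs
# ---------------------------------------------------------------------------

def simulate_nutrition_log(
    config: CohortConfig,
    participants: pd.DataFrame | None = None,
    study_start: _dt.date = DEFAULT_STUDY_START,
) -> pd.DataFrame:
    """One record per participant per day over the study window.

    Daily value of each metric = baseline + weekly_drift x (week-1) + noise,
    truncated at zero; week w covers days [7(w-1), 7w) from ``study_start``.
    """
    roster = simulate_participants(config) if participants is None else participants
    rng = _rng(config, _STREAM_NUTRITION)
    n_days = config.n_days
    metrics = list(config.nutrition_trend)

    rows = []
    for _, person in roster.iterrows():
        for day in range(n_days):
            week = day // 7  # 0-based
            row = {
                "participant_id": person["participant_id"],
                "date": (study_start + _dt.timedelta(days=day)).isoformat(),
            }
            for m in metrics:
                p = config.nutrition_trend[m]
                noise = rng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0
                row[m] = max(0.0, p.baseline + p.weekly_drift * week + noise)
            rows.append(row)
    return pd.DataFrame(rows)
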