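"""Kinematic metrics from wearable accelerometry.

Implements the segment-level physical-activity measures used in the analysis:

* z-score peak detection on the acceleration-magnitude series,
  z = (X - mu) / sigma, with a local-maximum requirement and a minimum
  peak separation (dead time);
* action count — detected peaks normalized by the number of samples;
* maximum acceleration — max(a) over the segment;
* RMS acceleration — sqrt(mean(a_i^2)), the movement-intensity proxy;
* metabolic equivalents — METs = 1.8 x RMS - 15 (clamped at zero; the raw
  value is preserved for auditing);
* energy expenditure — kcal = 1.05 x METs x D x W, with D the activity
  duration in hours and W the body mass in kg.

All metrics operate on the raw Euclidean norm of the tri-axial components;
gravity is not subtracted.  The MET regression is linear in RMS acceleration
with coefficients exposed for device-specific recalibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PeakDetectionConfig
from .errors import DegenerateSignalError, InputError
from .synthetic import SensorFrame

log = logging.getLogger(__name__)

#: Default MET regression: METs = MET_SLOPE * rms + MET_INTERCEPT.
MET_SLOPE = 1.8
MET_INTERCEPT = -15.0
#: Energy expenditure coefficient: kcal = KCAL_COEF * METs * hours * kg.
KCAL_COEF = 1.05

AGGREGATE = "AGGREGATE"


@dataclass(frozen=True)
class AccelSeries:
    """Scalar acceleration-magnitude series for one segment.

    ``values`` are per-sample Euclidean norms (m/s², all >= 0) and
    ``duration_h`` is the segment duration in hours.
    """

    values: np.ndarray
    duration_h: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise InputError("AccelSeries requires a 1-D series with n >= 1")
        if np.any(v < 0):
            raise InputError("acceleration magnitudes must be >= 0")
        if self.duration_h <= 0:
            raise InputError("duration_h must be > 0")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def dt_s(self) -> float:
        """Sample period in seconds."""
        return self.duration_h * 3600.0 / self.n


@dataclass(frozen=True)
class SegmentMetrics:
    """The kinematic metrics of one (participant, game, session) segment."""

    action_count: float
    max_acceleration: float
    rms_acceleration: float
    mets: float
    mets_raw: float
    energy_kcal: float
    peak_indices: np.ndarray = field(repr=False, default_factory=lambda: np.array([], int))


def magnitude(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    timestamps: np.ndarray | None = None,
    duration_s: float | None = None,
) -> AccelSeries:
    """Euclidean norm of the tri-axial components as an :class:`AccelSeries`.

    Duration is inferred from ``timestamps`` (n x the mean sample period) when
    given, otherwise ``duration_s`` must be supplied.
    """
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape) or ax.ndim != 1:
        raise InputError("component arrays must be 1-D and of equal length")
    if ax.size < 1:
        raise InputError("empty component arrays")
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        if t.shape != ax.shape:
            raise InputError("timestamps must match component length")
        if t.size >= 2:
            duration_s = float(t.size * (t[-1] - t[0]) / (t.size - 1))
        elif duration_s is None:
            raise InputError("duration_s required for a single-sample series")
    if duration_s is None:
        raise InputError("either timestamps or duration_s must be provided")
    values = np.sqrt(ax**2 + ay**2 + az**2)
    return AccelSeries(values=values, duration_h=duration_s / 3600.0)


def frame_magnitude(frame: SensorFrame) -> AccelSeries:
    """Magnitude series of a :class:`SensorFrame`."""
    return magnitude(frame.ax, frame.ay, frame.az, timestamps=frame.timestamps)


def zscore_series(series: AccelSeries, cfg: PeakDetectionConfig | None = None) -> np.ndarray:
    """Per-sample z-scores of the magnitude series.

    The reference mean and population standard deviation are taken over the
    whole segment (default) or over a centred rolling window of
    ``cfg.rolling_window_s`` seconds.

    Raises :class:`DegenerateSignalError` for a constant series (sigma = 0).
    """
    cfg = cfg or PeakDetectionConfig()
    x = series.values
    if cfg.windowing == "global":
        mu = float(np.mean(x))
        sigma = float(np.std(x))  # population sigma
        if sigma == 0.0:
            raise DegenerateSignalError("constant series: sigma = 0, z undefined")
        return (x - mu) / sigma
    # rolling: centred window, population sigma, window shrinks at the edges
    window = max(1, int(round(cfg.rolling_window_s / series.dt_s)))
    s = pd.Series(x)
    mu = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    sigma = s.rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    if np.all(sigma == 0):
        raise DegenerateSignalError("constant series: sigma = 0, z undefined")
    z = np.zeros_like(x)
    ok = sigma > 0
    z[ok] = (x[ok] - mu[ok]) / sigma[ok]
    return z


def detect_peaks(series: AccelSeries, cfg: PeakDetectionConfig | None = None) -> np.ndarray:
    """Indices of significant activity peaks in the magnitude series.

    A sample i is a peak candidate when z_i >= ``cfg.z_threshold`` and z_i is
    a local maximum (z_{i-1} <= z_i >= z_{i+1}; segment endpoints are never
    peaks).  Candidates are then filtered greedily in time order: a candidate
    is kept only if it is at least ``cfg.min_separation_s`` seconds after the
    previously kept peak, so the earlier of two close peaks wins (and on equal
    z within a separation window the first is kept).  The separation is
    enforced in whole samples (ceil of min_separation_s / sample period), so
    the boundary case is exact rather than float-dependent.

    A degenerate (constant) signal yields no peaks, with a logged warning.
    """
    cfg = cfg or PeakDetectionConfig()
    try:
        z = zscore_series(series, cfg)
    except DegenerateSignalError:
        log.warning("degenerate signal (zero variance): reporting zero peaks")
        return np.array([], dtype=int)
    n = series.n
    if n < 3:
        return np.array([], dtype=int)

    interior = z[1:-1]
    cand = (
        (interior >= cfg.z_threshold)
        & (z[:-2] <= interior)
        & (interior >= z[2:])
    )
    candidates = np.flatnonzero(cand) + 1
    if candidates.size == 0 or cfg.min_separation_s == 0:
        return candidates

    min_gap = max(1, int(np.ceil(cfg.min_separation_s / series.dt_s - 1e-9)))
    kept: list[int] = []
    last = -min_gap
    for i in candidates:
        if i - last >= min_gap:
            kept.append(int(i))
            last = int(i)
    return np.asarray(kept, dtype=int)


def action_count(peak_indices: np.ndarray, n: int) -> float:
    """Normalized peak count: number of detected peaks / number of samples."""
    if n < 1:
        raise InputError("n must be >= 1")
    return len(peak_indices) / n


def max_acceleration(series: AccelSeries) -> float:
    """Maximum of the acceleration-magnitude series (m/s²)."""
    return float(np.max(series.values))


def rms_acceleration(series: AccelSeries) -> float:
    """Root-mean-square of the acceleration-magnitude series (m/s²)."""
    return float(np.sqrt(np.mean(series.values**2)))


def mets_from_rms(
    rms: float, slope: float = MET_SLOPE, intercept: float = MET_INTERCEPT
) -> tuple[float, float]:
    """Metabolic equivalents from RMS acceleration.

    Returns ``(mets, mets_raw)``: the raw linear value ``slope*rms +
    intercept`` and its clamp at zero.  The linear map goes negative below
    rms = -intercept/slope; the clamp prevents negative energy estimates while
    the raw value remains available for auditing and recalibration.
    """
    if rms < 0:
        raise InputError("rms must be >= 0")
    raw = slope * rms + intercept
    return max(0.0, raw), raw


def energy_expenditure(
    mets: float, duration_h: float, weight_kg: float, coef: float = KCAL_COEF
) -> float:
    """Energy expenditure in kcal: coef x METs x duration (h) x weight (kg)."""
    if mets < 0 or duration_h < 0 or weight_kg < 0:
        raise InputError("mets, duration_h and weight_kg must all be >= 0")
    return coef * mets * duration_h * weight_kg


def segment_metrics(
    series: AccelSeries,
    cfg: PeakDetectionConfig | None = None,
    weight_kg: float = 65.0,
    met_slope: float = MET_SLOPE,
    met_intercept: float = MET_INTERCEPT,
) -> SegmentMetrics:
    """All kinematic metrics of one magnitude series."""
    peaks = detect_peaks(series, cfg)
    rms = rms_acceleration(series)
    mets, raw = mets_from_rms(rms, met_slope, met_intercept)
    return SegmentMetrics(
        action_count=action_count(peaks, series.n),
        max_acceleration=max_acceleration(series),
        rms_acceleration=rms,
        mets=mets,
        mets_raw=raw,
        energy_kcal=energy_expenditure(mets, series.duration_h, weight_kg),
        peak_indices=peaks,
    )


def session_metrics(
    frames: list[SensorFrame],
    cfg: PeakDetectionConfig | None = None,
    weight_kg: float = 65.0,
) -> dict[str, SegmentMetrics]:
    """Per-sensor metrics of one segment plus a cross-sensor aggregate.

    The aggregate (key ``"AGGREGATE"``) takes the mean action count and mean
    RMS across sensors, the maximum of the per-sensor maxima, and derives METs
    and energy from the aggregate RMS.

    All frames must share (participant, week, game).
    """
    if not frames:
        raise InputError("session_metrics requires at least one frame")
    identity = {(f.participant_id, f.session_week, f.game) for f in frames}
    if len(identity) != 1:
        raise InputError(f"mixed segment identities: {sorted(identity)}")

    per_sensor: dict[str, SegmentMetrics] = {}
    for f in frames:
        per_sensor[f.sensor_site] = segment_metrics(
            frame_magnitude(f), cfg, weight_kg=weight_kg
        )

    vals = list(per_sensor.values())
    agg_rms = float(np.mean([m.rms_acceleration for m in vals]))
    mets, raw = mets_from_rms(agg_rms)
    duration_h = frames[0].duration_s / 3600.0
    per_sensor[AGGREGATE] = SegmentMetrics(
        action_count=float(np.mean([m.action_count for m in vals])),
        max_acceleration=float(np.max([m.max_acceleration for m in vals])),
        rms_acceleration=agg_rms,
        mets=mets,
        mets_raw=raw,
        energy_kcal=energy_expenditure(mets, duration_h, weight_kg),
        peak_indices=np.array([], dtype=int),
    )
    return per_sensor


def cohort_metrics_table(
    frames: list[SensorFrame],
    cfg: PeakDetectionConfig | None = None,
    weights: dict[str, float] | None = None,
    include_sensors: bool = True,
) -> pd.DataFrame:
    """Metrics table for many frames, one row per sensor (and one AGGREGATE
    row) per (participant, week, game) segment.

    ``weights`` maps participant_id -> body mass in kg (default 65 kg).
    """
    by_segment: dict[tuple, list[SensorFrame]] = {}
    for f in frames:
        by_segment.setdefault((f.participant_id, f.session_week, f.game), []).append(f)

    rows = []
    for (pid, week, game), seg_frames in sorted(by_segment.items()):
        w = (weights or {}).get(pid, 65.0)
        metrics = session_metrics(seg_frames, cfg, weight_kg=w)
        # deterministic row order regardless of frame order: sites sorted,
        # aggregate last
        ordered = sorted(metrics.items(), key=lambda kv: (kv[0] == AGGREGATE, kv[0]))
        for site, m in ordered:
            if site != AGGREGATE and not include_sensors:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "week": week,
                    "game": game,
                    "sensor_site": site,
                    "action_count": round(m.action_count, 6),
                    "max_acc": round(m.max_acceleration, 4),
                    "rms_acc": round(m.rms_acceleration, 4),
                    "mets": round(m.mets, 4),
                    "energy_kcal": round(m.energy_kcal, 4),
                }
            )
    return pd.DataFrame(rows)
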