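"""Configuration objects for cohort simulation and analysis.

A single :class:`CohortConfig` document (YAML or JSON) governs every stage of
the pipeline: the synthetic cohort, the peak detector, the survey moments and
the nutrition drift parameters.  Every default encodes the study conditions the
analysis assumes — 48 participants across 4 arms, 30 pre/post survey
completers, 4 weekly sessions of 3 exergames at 10 minutes each, and 5
body-worn inertial sensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: The five standardized sensor placements: both distal forearms, the waist at
#: the L4 vertebral level, and the dorsum of each foot.
SENSOR_SITES = ("forearm_L", "forearm_R", "waist_L4", "foot_L", "foot_R")

#: Default exergame labels (upper-body slicing, lower-body stepping,
#: full-body boxing).
DEFAULT_GAMES = ("fruit_ninja", "piano_step", "arctic_punch")

DEFAULT_ARMS = (
    "conventional_exercise",
    "exergames_only",
    "exergames_coach",
    "exergames_peer",
)

WELL = "mentally_well"
MODERATE = "moderate"


@dataclass(frozen=True)
class PeakDetectionConfig:
    """Settings for z-score peak detection on an acceleration-magnitude series.

    z = (X - mu) / sigma with mu, sigma taken over the whole segment
    (``windowing="global"``, the default) or over a centred rolling window.
    sigma is the population standard deviation (divide by N).

    ``min_separation_s`` is the detector's dead time: of two candidate peaks
    closer than this, only the earlier is kept.  The default of 0.1 s resolves
    movement events at realistic exergame rates while still exceeding the
    above-threshold apex width of a typical impact burst, so a single burst is
    never counted twice.
    """

    z_threshold: float = 2.0
    min_separation_s: float = 0.1
    windowing: str = "global"  # "global" | "rolling"
    rolling_window_s: float = 5.0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be > 0")
        if self.min_separation_s < 0:
            raise ConfigurationError("min_separation_s must be >= 0")
        if self.windowing not in ("global", "rolling"):
            raise ConfigurationError(
                f"windowing must be 'global' or 'rolling', got {self.windowing!r}"
            )
        if self.windowing == "rolling" and self.rolling_window_s <= 0:
            raise ConfigurationError("rolling_window_s must be > 0")


@dataclass(frozen=True)
class SurveyItemParams:
    """Latent bivariate-normal moments for one pre/post Likert item.

    ``pre_mean``/``pre_sd`` and ``post_mean``/``post_sd`` are moments of the
    latent continuous responses *before* discretization and clipping;
    ``paired_correlation`` is the within-subject correlation of the pair.
    """

    item_id: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    paired_correlation: float = 0.5
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        if abs(self.paired_correlation) > 1:
            raise ConfigurationError(
                f"{self.item_id}: |paired_correlation| must be <= 1"
            )
        if self.pre_sd < 0 or self.post_sd < 0:
            raise ConfigurationError(f"{self.item_id}: SDs must be >= 0")
        if self.scale_min >= self.scale_max:
            raise ConfigurationError(f"{self.item_id}: scale_min must be < scale_max")


@dataclass(frozen=True)
class NutritionTrendParams:
    """Linear weekly drift model for one nutrition metric.

    Daily expectation in week w (1-based) is ``baseline + weekly_drift*(w-1)``
    with Gaussian day-to-day noise of SD ``noise_sd``, truncated at zero.
    """

    baseline: float
    weekly_drift: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.noise_sd < 0:
            raise ConfigurationError("nutrition baseline and noise_sd must be >= 0")


def _default_survey_items() -> tuple[SurveyItemParams, ...]:
    # Published pre/post moments of the seven technology-acceptance and
    # self-rated-health items, with a moderate within-subject correlation.
    rows = [
        ("Q1", 3.07, 0.78, 3.48, 0.70),
        ("Q2", 4.31, 1.05, 4.57, 0.79),
        ("Q3", 3.18, 0.79, 3.95, 0.82),
        ("Q4", 3.34, 0.77, 3.86, 0.67),
        ("Q5", 3.01, 0.70, 3.76, 0.68),
        ("Q6", 2.92, 0.84, 3.44, 0.73),
        ("Q7", 3.34, 0.72, 3.78, 0.66),
    ]
    return tuple(SurveyItemParams(i, a, b, c, d) for i, a, b, c, d in rows)


def _default_mhcsf_profile() -> dict[str, tuple[float, ...]]:
    # Per-item category probabilities over the 6-point frequency scale
    # (0 = never ... 5 = every day), one distribution per well-being group.
    # Flourishing participants concentrate on "every day" / "5-6 times a
    # week"; moderate participants on the middle of the scale.
    return {
        WELL: (0.01, 0.02, 0.05, 0.12, 0.35, 0.45),
        MODERATE: (0.10, 0.20, 0.30, 0.25, 0.10, 0.05),
    }


def _default_nutrition_trend() -> dict[str, NutritionTrendParams]:
    # Steady dairy intake, gradually rising hydration, strongly rising
    # balanced-meal logging over the four weeks.
    return {
        "milk_servings": NutritionTrendParams(baseline=1.5, weekly_drift=0.0, noise_sd=0.4),
        "water_cups": NutritionTrendParams(baseline=6.0, weekly_drift=0.5, noise_sd=1.0),
        "healthy_plate": NutritionTrendParams(baseline=1.0, weekly_drift=0.3, noise_sd=0.5),
    }


@dataclass
class CohortConfig:
    """Full description of a synthetic study cohort.

    The inertial signal model is baseline Gaussian sensor noise around gravity
    plus Poisson-timed half-sine movement bursts of ``burst_width_s`` seconds
    and ``peak_amplitude`` m/s² amplitude at an expected rate of
    ``peak_rate_hz`` events per second.  Per-week signal intensity is scaled
    linearly from 1 at week 1 to ``1 + group_intensity_growth[group]`` at the
    final week, so the expected maximum acceleration of a group changes by
    exactly that fraction over the study.
    """

    n_participants: int = 48
    n_survey_completers: int = 30
    arms: tuple[str, ...] = DEFAULT_ARMS
    weeks: int = 4
    games: tuple[str, ...] = DEFAULT_GAMES
    segment_duration_s: float = 600.0
    sampling_hz: float = 50.0
    seed: int = 0

    # IMU signal model
    peak_rate_hz: float = 0.5
    peak_amplitude: float = 8.0
    baseline_noise_sd: float = 0.3
    burst_width_s: float = 0.3
    gravity_ms2: float = 9.81
    group_intensity_growth: dict = field(
        default_factory=lambda: {WELL: 0.0214, MODERATE: 0.0960}
    )

    # cohort composition
    well_fraction: float = 0.5
    weight_mean_kg: float = 65.0
    weight_sd_kg: float = 10.0

    survey_item_params: tuple[SurveyItemParams, ...] = field(
        default_factory=_default_survey_items
    )
    mhcsf_profile: dict = field(default_factory=_default_mhcsf_profile)
    nutrition_trend: dict = field(default_factory=_default_nutrition_trend)

    def __post_init__(self) -> None:
        if self.n_survey_completers > self.n_participants:
            raise ConfigurationError(
                "n_survey_completers must be <= n_participants"
            )
        if self.sampling_hz <= 0 or self.segment_duration_s <= 0:
            raise ConfigurationError("sampling_hz and segment_duration_s must be > 0")
        if self.peak_rate_hz < 0:
            raise ConfigurationError("peak_rate_hz must be >= 0")
        if self.weeks < 1 or not self.games:
            raise ConfigurationError("weeks >= 1 and at least one game required")
        if not 0 <= self.well_fraction <= 1:
            raise ConfigurationError("well_fraction must be in [0, 1]")
        if self.peak_amplitude < 0 or self.baseline_noise_sd < 0:
            raise ConfigurationError("amplitude and noise SD must be >= 0")
        if self.burst_width_s <= 0:
            raise ConfigurationError("burst_width_s must be > 0")
        for group, probs in self.mhcsf_profile.items():
            rows = probs if probs and isinstance(probs[0], (list, tuple)) else [probs]
            for p in map(list, rows):
                if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"mhcsf_profile[{group!r}] must be probability vectors summing to 1"
                    )
        for metric, params in self.nutrition_trend.items():
            if not isinstance(params, NutritionTrendParams):
                raise ConfigurationError(
                    f"nutrition_trend[{metric!r}] must be NutritionTrendParams"
                )

    @property
    def samples_per_segment(self) -> int:
        return round(self.segment_duration_s * self.sampling_hz)

    @property
    def n_days(self) -> int:
        return 7 * self.weeks

    def intensity_scale(self, group: str, week: int) -> float:
        """Multiplicative signal scale for ``group`` in 1-based ``week``."""
        growth = float(self.group_intensity_growth.get(group, 0.0))
        if self.weeks == 1:
            return 1.0
        return 1.0 + growth * (week - 1) / (self.weeks - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        d["games"] = list(self.games)
        d["survey_item_params"] = [asdict(p) for p in self.survey_item_params]
        d["mhcsf_profile"] = {k: list(v) for k, v in self.mhcsf_profile.items()}
        d["nutrition_trend"] = {
            k: asdict(v) for k, v in self.nutrition_trend.items()
        }
        return d


def demo_config(seed: int = 0) -> CohortConfig:
    """A scaled-down cohort for quick end-to-end runs (short segments,
    reduced sampling rate, 8 participants); all statistical structure is
    unchanged."""
    return CohortConfig(
        n_participants=8,
        n_survey_completers=6,
        segment_duration_s=15.0,
        sampling_hz=25.0,
        seed=seed,
    )


def config_from_dict(doc: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain mapping (parsed YAML/JSON)."""
    doc = dict(doc)
    if "survey_item_params" in doc:
        doc["survey_item_params"] = tuple(
            SurveyItemParams(**p) for p in doc["survey_item_params"]
        )
    if "mhcsf_profile" in doc:
        doc["mhcsf_profile"] = {
            k: tuple(v) for k, v in doc["mhcsf_profile"].items()
        }
    if "nutrition_trend" in doc:
        doc["nutrition_trend"] = {
            k: NutritionTrendParams(**v) for k, v in doc["nutrition_trend"].items()
        }
    for key in ("arms", "games"):
        if key in doc:
            doc[key] = tuple(doc[key])
    try:
        return CohortConfig(**doc)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_config(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return config_from_dict(doc)
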