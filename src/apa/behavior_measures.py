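"""Objective activity and health measurement rules.

Covers the measurement pipeline surrounding the preference task:
accelerometer epoch classification (Evenson pediatric cut-points on 15-s
counts), daily summaries and wear-validity rules, direct-observation
scoring of a 30-min free-choice play period, VO2peak attainment criteria
on a graded exercise test, body-composition indices, and BMI-percentile
weight-status classes.  Wear/sleep annotation and BMI percentiles are
consumed as inputs; detecting non-wear or computing growth-reference
percentiles is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

EPOCH_SECONDS = 15
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS

# Evenson et al. pediatric cut-points, counts per 15-s epoch (inclusive)
SEDENTARY_MAX_CPE = 25
LIGHT_MAX_CPE = 573
MODERATE_MAX_CPE = 1002


class Intensity(str, Enum):
    SEDENTARY = "SEDENTARY"
    LIGHT = "LIGHT"
    MODERATE = "MODERATE"
    VIGOROUS = "VIGOROUS"


class WearState(str, Enum):
    AWAKE_WEAR = "AWAKE_WEAR"
    NON_WEAR = "NON_WEAR"
    SLEEP = "SLEEP"


class ObsCode(str, Enum):
    """Free-play observation codes; sedentary = not standing or moving."""

    SEDENTARY = "SEDENTARY"
    STANDING = "STANDING"
    MOVING = "MOVING"


def classify_epoch(counts):
    """Evenson intensity class for 15-s epoch counts.

    0-25 CPE sedentary, 26-573 light, 574-1002 moderate, >=1003 vigorous.
    Accepts a scalar (returns :class:`Intensity`) or an array (returns an
    object array of Intensity values).
    """
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    bins = [SEDENTARY_MAX_CPE + 1, LIGHT_MAX_CPE + 1, MODERATE_MAX_CPE + 1]
    order = np.array(
        [Intensity.SEDENTARY, Intensity.LIGHT, Intensity.MODERATE, Intensity.VIGOROUS],
        dtype=object,
    )
    idx = np.digitize(arr, bins)
    if np.isscalar(counts) or arr.ndim == 0:
        return order[int(idx)]
    return order[idx]


def validate_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    """Check an epoch table: strictly increasing uniform 15-s timestamps,
    non-negative counts, known wear states.  Returns the table with
    parsed dtypes."""
    out = epochs.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    dt = out["timestamp"].diff().dropna()
    if len(dt) and not (dt == pd.Timedelta(seconds=EPOCH_SECONDS)).all():
        raise ValueError("epochs must be strictly increasing at 15-s spacing")
    if (out["counts"] < 0).any():
        raise ValueError("counts must be non-negative")
    out["wear_state"] = out["wear_state"].map(WearState)
    if out["wear_state"].isna().any():
        raise ValueError("unknown wear_state value")
    return out


def summarize_days(epochs: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day intensity minutes over awake-wear epochs only.

    Sleep and non-wear epochs are excluded from every total, whatever
    their counts.  Each retained epoch contributes 0.25 min.  Returns a
    DataFrame indexed by ``date`` with columns ``awake_wear_min``,
    ``sedentary_min``, ``light_min``, ``moderate_min``, ``vigorous_min``,
    ``mvpa_min`` and ``is_weekend``.
    """
    ep = validate_epochs(epochs)
    ep["date"] = ep["timestamp"].dt.date
    rows = []
    for date, day in ep.groupby("date", sort=True):
        awake = day[day["wear_state"] == WearState.AWAKE_WEAR]
        mins = {i: 0.0 for i in Intensity}
        if len(awake):
            labels = np.array(
                [l.value for l in classify_epoch(awake["counts"].to_numpy())]
            )
            for i in Intensity:
                mins[i] = float(np.sum(labels == i.value)) / EPOCHS_PER_MINUTE
        rows.append(
            {
                "date": date,
                "awake_wear_min": len(awake) / EPOCHS_PER_MINUTE,
                "sedentary_min": mins[Intensity.SEDENTARY],
                "light_min": mins[Intensity.LIGHT],
                "moderate_min": mins[Intensity.MODERATE],
                "vigorous_min": mins[Intensity.VIGOROUS],
                "mvpa_min": mins[Intensity.MODERATE] + mins[Intensity.VIGOROUS],
                "is_weekend": pd.Timestamp(date).dayofweek >= 5,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WearValidityReport:
    """Day-level and overall wear-validity decision."""

    day_valid: tuple[bool, ...]
    n_valid_days: int
    n_valid_weekend_days: int
    overall_valid: bool


def check_wear_validity(
    summaries: pd.DataFrame,
    min_days: int = 4,
    min_hours: float = 10.0,
    min_weekend_days: int = 1,
) -> WearValidityReport:
    """Apply the wear-validity rule to daily summaries.

    A day is valid with at least ``min_hours`` of awake wear; the period
    is valid with at least ``min_days`` valid days of which at least
    ``min_weekend_days`` fall on a weekend.
    """
    valid = (summaries["awake_wear_min"] >= min_hours * 60).to_numpy()
    weekend = summaries["is_weekend"].to_numpy(dtype=bool)
    n_valid = int(valid.sum())
    n_valid_weekend = int((valid & weekend).sum())
    return WearValidityReport(
        day_valid=tuple(bool(v) for v in valid),
        n_valid_days=n_valid,
        n_valid_weekend_days=n_valid_weekend,
        overall_valid=n_valid >= min_days and n_valid_weekend >= min_weekend_days,
    )


def score_free_play(codes: Iterable[ObsCode | str]) -> float:
    """Percent of coded 15-s intervals spent sedentary.

    Standing and moving both count as non-sedentary.  A 30-min session
    has at most 120 intervals.
    """
    codes = [ObsCode(c) for c in codes]
    if not codes:
        raise ValueError("observation log is empty")
    if len(codes) > 120:
        raise ValueError(f"{len(codes)} intervals exceed a 30-min session")
    n_sed = sum(c == ObsCode.SEDENTARY for c in codes)
    return 100.0 * n_sed / len(codes)


def interrater_agreement(
    log_a: Iterable[ObsCode | str], log_b: Iterable[ObsCode | str]
) -> float:
    """Percent of intervals on which two observers coded identically."""
    a = [ObsCode(c) for c in log_a]
    b = [ObsCode(c) for c in log_b]
    if len(a) != len(b):
        raise ValueError(f"interval counts differ: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("observation logs are empty")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def default_hrmax(age: float) -> float:
    """Predicted maximal heart rate, 208 - 0.7*age (pediatric-appropriate)."""
    return 208.0 - 0.7 * age


# VO2peak attainment thresholds
PLATEAU_DELTA = 2.1  # mL/kg/min
RER_THRESHOLD = 1.0
HR_FRACTION = 0.90
RPE_THRESHOLD = 19


@dataclass(frozen=True)
class FitnessTest:
    """Graded cycle-ergometer test to volitional fatigue.

    ``stages`` holds one row per stage, ordered in time, with columns
    ``watts``, ``vo2_ml_kg_min``, ``rer``, ``hr``, ``rpe`` (6-20 scale);
    missing channels may be NaN.  ``weight_kg`` lets the weight-relative
    VO2 be re-expressed per kg fat-free mass.
    """

    stages: pd.DataFrame
    age: float
    ffm_kg: float
    weight_kg: float

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        if self.ffm_kg <= 0 or self.weight_kg <= 0:
            raise ValueError("masses must be positive")
        hr = self.stages["hr"].dropna()
        if (hr <= 0).any():
            raise ValueError("heart rate must be positive")


@dataclass(frozen=True)
class Vo2peakReport:
    """Which attainment criteria held, and the peak uptake per kg FFM.

    Criterion values are True/False, or None when the needed channel is
    missing (not evaluable); attainment requires at least two True.
    """

    plateau: bool | None
    rer: bool | None
    hr: bool | None
    rpe: bool | None
    n_met: int
    attained: bool
    vo2peak_ml_kg_min: float
    vo2peak_ffm: float


def vo2_per_ffm(vo2_l_min: float, ffm_kg: float) -> float:
    """Absolute VO2 (L/min) expressed as mL/kg fat-free mass/min."""
    return vo2_l_min * 1000.0 / ffm_kg


def check_vo2peak(
    test: FitnessTest,
    hrmax_model: Callable[[float], float] = default_hrmax,
    plateau_delta: float = PLATEAU_DELTA,
    rer_threshold: float = RER_THRESHOLD,
    hr_fraction: float = HR_FRACTION,
    rpe_threshold: float = RPE_THRESHOLD,
) -> Vo2peakReport:
    """Evaluate the four VO2peak attainment criteria.

    (1) plateau: on the final workload increment, the VO2 change is
    below ``plateau_delta`` mL/kg/min despite the higher load; (2) peak
    RER at or above ``rer_threshold``; (3) peak heart rate at or above
    ``hr_fraction`` of the model-predicted maximum; (4) peak RPE at or
    above ``rpe_threshold``.  VO2peak is attained when at least two
    criteria hold; a missing channel disables only its criterion.
    """
    st = test.stages

    def _crit(col: str, check) -> bool | None:
        vals = st[col].dropna()
        return None if vals.empty else bool(check(vals))

    vo2 = st["vo2_ml_kg_min"].to_numpy(dtype=float)
    watts = st["watts"].to_numpy(dtype=float)
    plateau: bool | None = None
    increments = [
        i
        for i in range(1, len(st))
        if watts[i] > watts[i - 1]
        and not (np.isnan(vo2[i]) or np.isnan(vo2[i - 1]))
    ]
    if increments:
        i = increments[-1]
        plateau = bool(vo2[i] - vo2[i - 1] < plateau_delta)

    rer = _crit("rer", lambda v: v.max() >= rer_threshold)
    hr = _crit("hr", lambda v: v.max() >= hr_fraction * hrmax_model(test.age))
    rpe = _crit("rpe", lambda v: v.max() >= rpe_threshold)

    met = [c for c in (plateau, rer, hr, rpe) if c is True]
    vo2peak = float(np.nanmax(vo2))
    return Vo2peakReport(
        plateau=plateau,
        rer=rer,
        hr=hr,
        rpe=rpe,
        n_met=len(met),
        attained=len(met) >= 2,
        vo2peak_ml_kg_min=vo2peak,
        vo2peak_ffm=vo2peak * test.weight_kg / test.ffm_kg,
    )


def body_composition(
    fat_kg: float, weight_kg: float, height_m: float
) -> tuple[float, float]:
    """Percent body fat and fat mass index from DXA-derived fat mass.

    %BF = 100 * fat / weight; FMI = fat / height^2 (kg/m^2).
    """
    if fat_kg <= 0 or weight_kg <= 0 or height_m <= 0:
        raise ValueError("inputs must be positive")
    if fat_kg > weight_kg:
        raise ValueError("fat mass cannot exceed body weight")
    return 100.0 * fat_kg / weight_kg, fat_kg / height_m**2


class WeightStatus(str, Enum):
    UNDERWEIGHT = "UNDERWEIGHT"
    HEALTHY = "HEALTHY"
    OVERWEIGHT = "OVERWEIGHT"
    OBESITY = "OBESITY"
    SEVERE_OBESITY = "SEVERE_OBESITY"


@dataclass(frozen=True)
class WeightClassification:
    category: WeightStatus
    severe_undetermined: bool = False


def classify_weight_status(
    bmi: float,
    bmi_percentile: float,
    bmi_at_p95: float | None = None,
    underweight_percentile: float = 5.0,
) -> WeightClassification:
    """BMI-percentile weight-status class.

    Overweight at percentile >=85 and <95; obesity at >=95; severe
    obesity when BMI reaches 120% of the 95th-percentile BMI for age and
    sex (``bmi_at_p95``, supplied by a growth-reference provider).  Below
    ``underweight_percentile`` (default 5) is underweight.  When the
    percentile is >=95 but ``bmi_at_p95`` is unavailable the class is
    OBESITY with ``severe_undetermined`` set.
    """
    if not 0.0 <= bmi_percentile <= 100.0:
        raise ValueError("bmi_percentile must be in [0, 100]")
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if bmi_percentile < underweight_percentile:
        return WeightClassification(WeightStatus.UNDERWEIGHT)
    if bmi_percentile < 85.0:
        return WeightClassification(WeightStatus.HEALTHY)
    if bmi_percentile < 95.0:
        return WeightClassification(WeightStatus.OVERWEIGHT)
    if bmi_at_p95 is None:
        return WeightClassification(WeightStatus.OBESITY, severe_undetermined=True)
    if bmi_at_p95 <= 0:
        raise ValueError("bmi_at_p95 must be positive")
    if bmi >= 1.2 * bmi_at_p95:
        return WeightClassification(WeightStatus.SEVERE_OBESITY)
    return WeightClassification(WeightStatus.OBESITY)
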