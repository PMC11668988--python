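"""Minute-level intensity classification under three algorithms.

Each observed minute receives exactly one label per algorithm:

* ``step``  -- cadence thresholds (steps/min) for light/moderate/vigorous;
* ``hr``    -- heart rate as a fraction of predicted maximum heart rate
  (intercept - slope*age, age in completed years on the observation date);
* ``device`` -- the device's own sedentary / lightly_active / fairly_active /
  very_active labels mapped onto the same four intensities.

Thresholds are inclusive at the lower edge of the higher category.  Minutes
missing the algorithm's required signal are ``unclassifiable``: they carry no
intensity but still count as wear.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import DEVICE_LABELS

__all__ = [
    "LABELS",
    "METHODS",
    "CODE_ABSENT",
    "CODE_UNCLASSIFIABLE",
    "CODE_SEDENTARY",
    "CODE_LIGHT",
    "CODE_MODERATE",
    "CODE_VIGOROUS",
    "IntensityProfile",
    "step_intensity",
    "hr_intensity",
    "device_intensity",
    "max_heart_rate",
    "step_codes",
    "hr_codes",
    "device_codes",
    "minute_codes",
    "day_code_grid",
    "daily_profile",
]

METHODS = ("step", "hr", "device")
LABELS = ("sedentary", "light", "moderate", "vigorous", "unclassifiable")

# integer codes used on per-day minute grids
CODE_ABSENT = -2  # no record for the minute (nonwear)
CODE_UNCLASSIFIABLE = -1
CODE_SEDENTARY = 0
CODE_LIGHT = 1
CODE_MODERATE = 2
CODE_VIGOROUS = 3

_CODE_TO_LABEL = {
    CODE_UNCLASSIFIABLE: "unclassifiable",
    CODE_SEDENTARY: "sedentary",
    CODE_LIGHT: "light",
    CODE_MODERATE: "moderate",
    CODE_VIGOROUS: "vigorous",
}

_DEVICE_TO_CODE = {
    "sedentary": CODE_SEDENTARY,
    "lightly_active": CODE_LIGHT,
    "fairly_active": CODE_MODERATE,
    "very_active": CODE_VIGOROUS,
}


@dataclass(frozen=True)
class IntensityProfile:
    """Per-day minute counts for one participant under one algorithm."""

    participant_id: str
    date: dt.date
    method: str
    minutes: Dict[str, int]

    @property
    def wear_minutes(self) -> int:
        return sum(self.minutes.values())


# -- scalar classifiers ---------------------------------------------------


def step_intensity(steps, config: PipelineConfig) -> str:
    """Label one minute from its cadence (steps/min)."""
    if steps is None or (isinstance(steps, float) and np.isnan(steps)):
        return "unclassifiable"
    if steps < 0:
        raise ValueError(f"negative steps ({steps}); should have been dropped at ingest")
    light, moderate, vigorous = config.step_thresholds
    if steps >= vigorous:
        return "vigorous"
    if steps >= moderate:
        return "moderate"
    if steps >= light:
        return "light"
    return "sedentary"


def max_heart_rate(age_years, config: PipelineConfig) -> float:
    """Predicted maximum heart rate: intercept - slope * age (no rounding)."""
    if age_years < 18:
        raise ValueError(f"age must be >= 18, got {age_years}")
    return config.max_hr_intercept - config.max_hr_slope * age_years


def hr_intensity(heart_rate, max_hr: float, config: PipelineConfig) -> str:
    """Label one minute from its heart rate relative to ``max_hr``."""
    if heart_rate is None or (isinstance(heart_rate, float) and np.isnan(heart_rate)):
        return "unclassifiable"
    if heart_rate <= 0:
        raise ValueError(f"heart rate must be positive, got {heart_rate}")
    if max_hr <= 0:
        raise ValueError(f"max heart rate must be positive, got {max_hr}")
    f = heart_rate / max_hr
    light, moderate, vigorous = config.hr_fractions
    if f >= vigorous:
        return "vigorous"
    if f >= moderate:
        return "moderate"
    if f >= light:
        return "light"
    return "sedentary"


def device_intensity(device_label, config: PipelineConfig) -> str:
    """Map a device label onto the common intensity vocabulary."""
    if device_label is None or (
        isinstance(device_label, float) and np.isnan(device_label)
    ):
        return "unclassifiable"
    try:
        return _CODE_TO_LABEL[_DEVICE_TO_CODE[device_label]]
    except KeyError:
        raise ValueError(
            f"unknown device label {device_label!r}; expected one of {list(DEVICE_LABELS)}"
        ) from None


# -- vectorised classifiers ----------------------------------------------


def step_codes(steps: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Vectorised cadence classification; NaN -> unclassifiable."""
    steps = np.asarray(steps, dtype=float)
    light, moderate, vigorous = config.step_thresholds
    codes = np.full(steps.shape, CODE_UNCLASSIFIABLE, dtype=np.int8)
    present = ~np.isnan(steps)
    if np.any(steps[present] < 0):
        raise ValueError("negative steps encountered; should have been dropped at ingest")
    codes[present] = CODE_SEDENTARY
    codes[present & (steps >= light)] = CODE_LIGHT
    codes[present & (steps >= moderate)] = CODE_MODERATE
    codes[present & (steps >= vigorous)] = CODE_VIGOROUS
    return codes


def hr_codes(
    heart_rate: np.ndarray, max_hr: float, config: PipelineConfig
) -> np.ndarray:
    """Vectorised %HRmax classification; NaN -> unclassifiable."""
    heart_rate = np.asarray(heart_rate, dtype=float)
    if max_hr <= 0:
        raise ValueError("max heart rate must be positive")
    f = heart_rate / max_hr
    light, moderate, vigorous = config.hr_fractions
    codes = np.full(f.shape, CODE_UNCLASSIFIABLE, dtype=np.int8)
    present = ~np.isnan(f)
    codes[present] = CODE_SEDENTARY
    codes[present & (f >= light)] = CODE_LIGHT
    codes[present & (f >= moderate)] = CODE_MODERATE
    codes[present & (f >= vigorous)] = CODE_VIGOROUS
    return codes


def device_codes(labels: pd.Series, config: PipelineConfig) -> np.ndarray:
    """Vectorised device-label mapping; missing -> unclassifiable."""
    values = labels.to_numpy(dtype=object)
    codes = np.full(len(values), CODE_UNCLASSIFIABLE, dtype=np.int8)
    for i, value in enumerate(values):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        try:
            codes[i] = _DEVICE_TO_CODE[value]
        except KeyError:
            raise ValueError(
                f"unknown device label {value!r}; expected one of {list(DEVICE_LABELS)}"
            ) from None
    return codes


def minute_codes(
    day_minutes: pd.DataFrame,
    method: str,
    age_years: int,
    config: PipelineConfig,
) -> np.ndarray:
    """Intensity codes for the observed minutes of one day, one method."""
    if method == "step":
        return step_codes(day_minutes["steps"].to_numpy(), config)
    if method == "hr":
        return hr_codes(
            day_minutes["heart_rate"].to_numpy(),
            max_heart_rate(age_years, config),
            config,
        )
    if method == "device":
        return device_codes(day_minutes["device_label"], config)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def day_code_grid(
    day_minutes: pd.DataFrame,
    method: str,
    age_years: int,
    config: PipelineConfig,
) -> np.ndarray:
    """Lay one day's codes onto the contiguous wake-period minute grid.

    The sleep window removes both ends of a midnight-anchored day, so the
    surviving minutes form one contiguous block (05:00..22:59 by default).
    Grid slots with no record are CODE_ABSENT; absent minutes are nonwear
    and count as inactive for bout detection.
    """
    start, end = config.wake_grid
    grid = np.full(end - start, CODE_ABSENT, dtype=np.int8)
    if day_minutes.empty:
        return grid
    codes = minute_codes(day_minutes, method, age_years, config)
    minute_of_day = (
        day_minutes["datetime"].dt.hour * 60 + day_minutes["datetime"].dt.minute
    ).to_numpy()
    if np.any((minute_of_day < start) | (minute_of_day >= end)):
        raise ValueError("day contains minutes inside the sleep window; exclude first")
    grid[minute_of_day - start] = codes
    return grid


def daily_profile(
    day_minutes: pd.DataFrame,
    method: str,
    participant_id: str,
    date: dt.date,
    age_years: int,
    config: PipelineConfig,
) -> IntensityProfile:
    """Count a day's wear minutes per intensity label for one method."""
    codes = minute_codes(day_minutes, method, age_years, config)
    counts = {
        label: int(np.sum(codes == code))
        for code, label in _CODE_TO_LABEL.items()
    }
    return IntensityProfile(
        participant_id=participant_id, date=date, method=method, minutes=counts
    )
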