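"""Run configuration for the activity-processing pipeline.

All numeric constants used by the processing stages live here so that a run
is fully described by one :class:`PipelineConfig` value.  The defaults
reproduce the published analysis parameters: a 23:00-05:00 presumed-sleep
window, valid wear days with >=600 heart-rate minutes and >=100 steps, valid
weeks with >=3 valid days anchored on January 1, cadence thresholds of
60/100/130 steps per minute, heart-rate fractions of 0.57/0.64/0.77 of
predicted maximum heart rate (208 - 0.7*age), a 150 minutes/week MVPA target
with vigorous minutes weighted twice, >=10-minute bouts tolerating <=2
interruption minutes, and small-cell suppression below 20 participants.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Any, Mapping, Tuple

import yaml

__all__ = ["PipelineConfig"]


def _parse_time(value: Any) -> dt.time:
    if isinstance(value, dt.time):
        return value
    if isinstance(value, str):
        hh, mm = value.split(":")
        return dt.time(int(hh), int(mm))
    raise TypeError(f"cannot interpret {value!r} as a clock time")


@dataclass(frozen=True)
class PipelineConfig:
    """Immutable bundle of every tunable used by the pipeline."""

    sleep_window_start: dt.time = dt.time(23, 0)
    sleep_window_end: dt.time = dt.time(5, 0)
    min_hr_minutes_per_day: int = 600
    min_steps_per_day: int = 100
    min_valid_days_per_week: int = 3
    # steps/min at or above which a minute is light / moderate / vigorous
    step_thresholds: Tuple[float, float, float] = (60.0, 100.0, 130.0)
    # fraction of predicted max HR at or above which a minute is
    # light / moderate / vigorous
    hr_fractions: Tuple[float, float, float] = (0.57, 0.64, 0.77)
    max_hr_intercept: float = 208.0
    max_hr_slope: float = 0.7  # bpm lost per year of age
    mvpa_target: float = 150.0  # minutes/week
    vpa_weight: float = 2.0  # vigorous minutes count this many moderate minutes
    bout_min_duration: int = 10  # minutes
    bout_max_interruption: int = 2  # cumulative inactive minutes per bout
    weekly_scaling: str = "extrapolate"  # or "raw_sum"
    bmi_lower_outlier: float = 12.0  # kg/m^2
    bmi_upper_outlier: float = 150.0  # kg/m^2
    bmi_underweight_cutoff: float = 18.5  # kg/m^2
    suppression_threshold: int = 20  # participants
    alpha_primary: float = 0.05
    alpha_chisq: float = 0.0012
    alpha_mcnemar: float = 0.0008
    continuity_correction: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sleep_window_start", _parse_time(self.sleep_window_start)
        )
        object.__setattr__(self, "sleep_window_end", _parse_time(self.sleep_window_end))
        object.__setattr__(self, "step_thresholds", tuple(self.step_thresholds))
        object.__setattr__(self, "hr_fractions", tuple(self.hr_fractions))
        self._validate()

    def _validate(self) -> None:
        lo, mo, vi = self.step_thresholds
        if not (0 < lo < mo < vi):
            raise ValueError(
                f"step thresholds must be positive and strictly increasing, "
                f"got {self.step_thresholds}"
            )
        flo, fmo, fvi = self.hr_fractions
        if not (0 < flo < fmo < fvi):
            raise ValueError(
                f"hr fractions must be positive and strictly increasing, "
                f"got {self.hr_fractions}"
            )
        for name in (
            "min_hr_minutes_per_day",
            "min_steps_per_day",
            "min_valid_days_per_week",
            "mvpa_target",
            "vpa_weight",
            "bout_min_duration",
            "suppression_threshold",
            "max_hr_intercept",
            "max_hr_slope",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bout_max_interruption < 0:
            raise ValueError("bout_max_interruption must be >= 0")
        if self.sleep_window_start <= self.sleep_window_end:
            raise ValueError(
                "sleep window must be overnight (start later in the day than end)"
            )
        if self.weekly_scaling not in ("extrapolate", "raw_sum"):
            raise ValueError(
                f"weekly_scaling must be 'extrapolate' or 'raw_sum', "
                f"got {self.weekly_scaling!r}"
            )
        if not self.bmi_lower_outlier < self.bmi_underweight_cutoff < self.bmi_upper_outlier:
            raise ValueError("BMI cutoffs must be ordered lower < underweight < upper")
        for name in ("alpha_primary", "alpha_chisq", "alpha_mcnemar"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    # -- sleep window geometry -------------------------------------------

    @property
    def sleep_minutes_per_day(self) -> int:
        """Minute slots removed from each calendar day by the sleep window."""
        start = self.sleep_window_start.hour * 60 + self.sleep_window_start.minute
        end = self.sleep_window_end.hour * 60 + self.sleep_window_end.minute
        return (1440 - start) + end

    @property
    def wake_grid(self) -> Tuple[int, int]:
        """Half-open minute-of-day range [start, end) that survives exclusion."""
        start = self.sleep_window_end.hour * 60 + self.sleep_window_end.minute
        end = self.sleep_window_start.hour * 60 + self.sleep_window_start.minute
        return start, end

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sleep_window_start"] = self.sleep_window_start.strftime("%H:%M")
        d["sleep_window_end"] = self.sleep_window_end.strftime("%H:%M")
        d["step_thresholds"] = list(self.step_thresholds)
        d["hr_fractions"] = list(self.hr_fractions)
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **overrides: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)
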