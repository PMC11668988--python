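from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wearpa.config import PipelineConfig


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def make_minutes(
    rows,
    person_id: str = "P1",
) -> pd.DataFrame:
    """Build a minute frame from (datetime-str, steps, heart_rate[, label]) rows."""
    records = []
    for row in rows:
        stamp, steps, hr = row[0], row[1], row[2]
        label = row[3] if len(row) > 3 else None
        records.append(
            {
                "person_id": person_id,
                "datetime": pd.Timestamp(stamp),
                "steps": float(steps) if steps is not None else np.nan,
                "heart_rate": float(hr) if hr is not None else np.nan,
                "device_label": label,
            }
        )
    return pd.DataFrame(records)


def full_day(
    date: str,
    steps: float = 10,
    heart_rate: float = 80.0,
    label: str = "sedentary",
    person_id: str = "P1",
    start_minute: int = 300,
    n_minutes: int = 1080,
) -> pd.DataFrame:
    """A contiguous block of identical minutes on one day (post-sleep grid)."""
    base = pd.Timestamp(date)
    stamps = base + pd.to_timedelta(np.arange(start_minute, start_minute + n_minutes), unit="m")
    return pd.DataFrame(
        {
            "person_id": person_id,
            "datetime": stamps,
            "steps": float(steps),
            "heart_rate": float(heart_rate),
            "device_label": label,
        }
    )


@pytest.fixture
def minutes_factory():
    return make_minutes


@pytest.fixture
def day_factory():
    return full_day
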