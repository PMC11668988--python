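"""Readers and writers for the pipeline's tabular formats.

Minute data arrive as long/tidy CSV with one row per observed device-minute;
minutes absent from the file are nonwear.  Demographics arrive as one row per
participant plus an optional long companion table of dated BMI measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MINUTE_COLUMNS",
    "DEVICE_LABELS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "ParseReport",
    "read_minute_data",
    "read_demographics",
    "iter_participants",
]

MINUTE_COLUMNS = ["person_id", "datetime", "steps", "heart_rate", "device_label"]
DEVICE_LABELS = ("sedentary", "lightly_active", "fairly_active", "very_active")
SEX_LEVELS = ("male", "female", "other_or_not_specified")
RACE_LEVELS = (
    "hispanic",
    "nh_asian_pi",
    "nh_black",
    "nh_white",
    "two_or_more",
    "other_or_not_specified",
)


@dataclass
class ParseReport:
    """Row accounting for one ingest: rows in = rows kept + rows dropped."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: Dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class DuplicateMinuteError(ValueError):
    """Two rows share the same (participant, timestamp)."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_minute_data(
    path, config=None
) -> Tuple[pd.DataFrame, ParseReport]:
    """Read a minute-level CSV, validating row by row.

    Returns a frame sorted by (person_id, datetime) with columns
    ``person_id`` (str), ``datetime`` (ns timestamps, naive local clock time),
    ``steps`` (float, NaN when missing), ``heart_rate`` (float, NaN when
    missing) and ``device_label`` (str or NaN), plus a :class:`ParseReport`.

    Row-level domain violations (malformed timestamp, negative steps,
    non-positive heart rate, unknown device label) drop the row and are
    tallied in the report.  Duplicate (participant, timestamp) pairs are a
    hard failure: they indicate a corrupted export rather than a bad row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"person_id": str, "device_label": str})
    _require_columns(df, MINUTE_COLUMNS, path)
    report = ParseReport(rows_read=len(df))

    ts = pd.to_datetime(df["datetime"], errors="coerce", format="ISO8601")
    steps = pd.to_numeric(df["steps"], errors="coerce")
    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    label = df["device_label"]

    # one drop reason per row, assigned in priority order
    conditions = [
        ts.isna(),
        steps.isna() & df["steps"].notna(),
        steps < 0,
        hr.isna() & df["heart_rate"].notna(),
        hr <= 0,
        label.notna() & ~label.isin(DEVICE_LABELS),
    ]
    reasons = [
        "malformed_timestamp",
        "unparseable_steps",
        "negative_steps",
        "unparseable_heart_rate",
        "nonpositive_heart_rate",
        "unknown_device_label",
    ]
    reason = np.select(conditions, reasons, default="")
    for name in reasons:
        report.drop(name, int((reason == name).sum()))
    keep = reason == ""
    out = pd.DataFrame(
        {
            "person_id": df.loc[keep, "person_id"].astype(str),
            "datetime": ts[keep].dt.floor("min"),
            "steps": steps[keep],
            "heart_rate": hr[keep],
            "device_label": label[keep],
        }
    )

    dup = out.duplicated(subset=["person_id", "datetime"], keep=False)
    if dup.any():
        first = out.loc[dup].iloc[0]
        raise DuplicateMinuteError(
            f"duplicate minute for participant {first['person_id']} "
            f"at {first['datetime']}"
        )

    out = out.sort_values(["person_id", "datetime"], kind="mergesort").reset_index(
        drop=True
    )
    report.rows_kept = len(out)
    assert report.rows_read == report.rows_kept + report.rows_dropped
    return out, report


def read_demographics(
    demo_path, bmi_path=None
) -> pd.DataFrame:
    """Read the participant table and attach BMI measurements.

    ``demo_path`` must provide person_id, sex, race_ethnicity, birth_date.
    ``bmi_path``, when given, is a long table of person_id, bmi_date,
    bmi_value rows; measurements are attached unfiltered, in date order
    (outlier and window filtering happen later in the pipeline).

    Category vocabularies are strict: any unknown sex or race/ethnicity
    value is a hard failure listing the offending value.
    """
    demo_path = Path(demo_path)
    demo = pd.read_csv(demo_path, dtype={"person_id": str})
    _require_columns(demo, ["person_id", "sex", "race_ethnicity", "birth_date"], demo_path)

    if demo["person_id"].duplicated().any():
        dupes = demo.loc[demo["person_id"].duplicated(), "person_id"].tolist()
        raise ValueError(f"{demo_path}: duplicate person_id(s): {dupes}")

    bad_sex = demo.loc[~demo["sex"].isin(SEX_LEVELS), "sex"]
    if len(bad_sex):
        raise ValueError(
            f"{demo_path}: unknown sex value(s) {sorted(set(bad_sex))}; "
            f"expected one of {list(SEX_LEVELS)}"
        )
    bad_race = demo.loc[~demo["race_ethnicity"].isin(RACE_LEVELS), "race_ethnicity"]
    if len(bad_race):
        raise ValueError(
            f"{demo_path}: unknown race_ethnicity value(s) {sorted(set(bad_race))}; "
            f"expected one of {list(RACE_LEVELS)}"
        )

    birth = pd.to_datetime(demo["birth_date"], errors="coerce", format="ISO8601")
    if birth.isna().any():
        bad = demo.loc[birth.isna(), "birth_date"].tolist()
        raise ValueError(f"{demo_path}: unparseable birth_date value(s) {bad}")

    out = pd.DataFrame(
        {
            "person_id": demo["person_id"].astype(str),
            "sex": demo["sex"],
            "race_ethnicity": demo["race_ethnicity"],
            "birth_date": birth.dt.date,
        }
    )

    measurements: Dict[str, list] = {pid: [] for pid in out["person_id"]}
    if bmi_path is not None:
        bmi_path = Path(bmi_path)
        bmi = pd.read_csv(bmi_path, dtype={"person_id": str})
        _require_columns(bmi, ["person_id", "bmi_date", "bmi_value"], bmi_path)
        dates = pd.to_datetime(bmi["bmi_date"], errors="coerce", format="ISO8601")
        if dates.isna().any():
            bad = bmi.loc[dates.isna(), "bmi_date"].tolist()
            raise ValueError(f"{bmi_path}: unparseable bmi_date value(s) {bad}")
        values = pd.to_numeric(bmi["bmi_value"], errors="coerce")
        if values.isna().any():
            bad = bmi.loc[values.isna(), "bmi_value"].tolist()
            raise ValueError(f"{bmi_path}: unparseable bmi_value(s) {bad}")
        for pid, day, value in sorted(
            zip(bmi["person_id"].astype(str), dates.dt.date, values),
            key=lambda t: (t[0], t[1]),
        ):
            if pid in measurements:
                measurements[pid].append((day, float(value)))

    out["bmi_measurements"] = [measurements[pid] for pid in out["person_id"]]
    return out.sort_values("person_id", kind="mergesort").reset_index(drop=True)


def iter_participants(minutes: pd.DataFrame) -> Iterator[Tuple[str, pd.DataFrame]]:
    """Yield (person_id, minute frame) in sorted participant order."""
    for pid, group in minutes.groupby("person_id", sort=True):
        yield str(pid), group
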