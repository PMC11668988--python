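"""End-to-end orchestration: minute CSVs in, adherence and statistics out.

Stage order mirrors the processing workflow: ingest -> under-18 exclusion ->
sleep-window removal -> wear calendar -> age-group restriction -> BMI
classification -> intensity profiles -> weekly MVPA and bouts -> adherence
-> cohort statistics.  A JSON manifest records the effective configuration
and the attrition count at every stage.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import stats as st
from .adherence import (
    AdherenceResult,
    day_bouted_weighted_mvpa,
    day_weighted_mvpa,
    participant_adherence,
    weekly_mvpa,
)
from .config import PipelineConfig
from .intensity import METHODS, day_code_grid
from .io import ParseReport, read_demographics, read_minute_data
from .stats import (
    assign_age_group,
    classify_bmi,
    filter_adult_minutes,
)
from .timeutil import completed_years
from .wear import build_wear_calendar, exclude_sleep_window, week_start_date

__all__ = ["PipelineError", "ProcessResult", "process_cohort", "run_pipeline"]

SUPPRESSED_TOKEN = "SUPPRESSED"

REFERENCES = {
    "sex": "male",
    "race_ethnicity": "nh_white",
    "bmi_category": "normal",
    "age_group": "18-29",
}
FACTORS = ("sex", "race_ethnicity", "bmi_category", "age_group")


class PipelineError(RuntimeError):
    pass


@dataclass
class ProcessResult:
    adherence: pd.DataFrame  # one row per participant x method
    participants: pd.DataFrame  # one row per included participant
    attrition: Dict[str, int]

    def method_frame(self, method: str) -> pd.DataFrame:
        sub = self.adherence.loc[self.adherence["method"] == method]
        return sub.merge(self.participants, on="person_id", validate="one_to_one")


def _process_participant(
    pid: str,
    minutes: pd.DataFrame,
    birth_date: dt.date,
    bmi_measurements,
    config: PipelineConfig,
    attrition: Dict[str, int],
) -> Optional[Tuple[List[AdherenceResult], dict]]:
    adult = filter_adult_minutes(minutes, birth_date)
    attrition["minutes_under_18_removed"] += len(minutes) - len(adult)
    awake, removed = exclude_sleep_window(adult, config)
    attrition["sleep_window_minutes_removed"] += removed

    calendar = build_wear_calendar(awake, pid, config)
    if not calendar.include:
        return None

    age_group, kept_weeks = assign_age_group(birth_date, calendar.valid_weeks, config)
    attrition["valid_weeks_outside_age_group_dropped"] += len(
        calendar.valid_weeks
    ) - len(kept_weeks)

    first_week_start = week_start_date(*kept_weeks[0])
    last_week_end = week_start_date(*kept_weeks[-1]) + dt.timedelta(days=6)
    bmi_category, bmi_mean = classify_bmi(
        bmi_measurements, first_week_start, last_week_end, config
    )

    by_day = {day: frame for day, frame in awake.groupby(awake["datetime"].dt.date)}
    results = []
    for method in METHODS:
        week_values: Dict[Tuple[int, int], Tuple[float, float]] = {}
        for week in kept_weeks:
            record = calendar.week_records[week]
            daily_mvpa: List[float] = []
            daily_bouted: List[float] = []
            for day in record.valid_days:
                age = completed_years(birth_date, day)
                grid = day_code_grid(by_day[day], method, age, config)
                daily_mvpa.append(day_weighted_mvpa(grid, config))
                daily_bouted.append(day_bouted_weighted_mvpa(grid, config))
            week_values[week] = (
                weekly_mvpa(daily_mvpa, config),
                weekly_mvpa(daily_bouted, config),
            )
        results.append(participant_adherence(pid, method, week_values, config))

    meta = {
        "person_id": pid,
        "age_group": age_group,
        "bmi_category": bmi_category,
        "bmi_mean": bmi_mean,
        "n_valid_weeks": len(kept_weeks),
    }
    return results, meta


def process_cohort(
    minutes: pd.DataFrame,
    demographics: pd.DataFrame,
    config: PipelineConfig,
    parse_report: Optional[ParseReport] = None,
) -> ProcessResult:
    """Run every per-participant stage and assemble cohort-level tables."""
    attrition: Dict[str, int] = {
        "minute_rows_read": parse_report.rows_read if parse_report else len(minutes),
        "minute_rows_dropped_at_parse": parse_report.rows_dropped if parse_report else 0,
        "minutes_under_18_removed": 0,
        "sleep_window_minutes_removed": 0,
        "valid_weeks_outside_age_group_dropped": 0,
        "participants_in_demographics": len(demographics),
        "participants_with_minute_data": 0,
        "participants_without_valid_week": 0,
        "participants_included": 0,
    }
    demo = demographics.set_index("person_id")

    adherence_rows = []
    participant_rows = []
    for pid, group in minutes.groupby("person_id", sort=True):
        pid = str(pid)
        if pid not in demo.index:
            raise PipelineError(f"participant {pid} has minute data but no demographics")
        attrition["participants_with_minute_data"] += 1
        row = demo.loc[pid]
        outcome = _process_participant(
            pid,
            group.reset_index(drop=True),
            row["birth_date"],
            row["bmi_measurements"],
            config,
            attrition,
        )
        if outcome is None:
            attrition["participants_without_valid_week"] += 1
            continue
        results, meta = outcome
        attrition["participants_included"] += 1
        meta["sex"] = row["sex"]
        meta["race_ethnicity"] = row["race_ethnicity"]
        participant_rows.append(meta)
        for res in results:
            row = dataclasses.asdict(res)
            row["person_id"] = row.pop("participant_id")
            adherence_rows.append(row)

    if attrition["participants_included"] == 0:
        table = "\n".join(f"  {k}: {v}" for k, v in attrition.items())
        raise PipelineError(
            "no participant survived wear validation; attrition by stage:\n" + table
        )

    adherence = pd.DataFrame(adherence_rows)[
        [
            "person_id",
            "method",
            "weekly_mvpa_2018",
            "weekly_bouted_mvpa_2008",
            "meets_2018",
            "meets_2008",
        ]
    ]
    participants = pd.DataFrame(participant_rows)[
        [
            "person_id",
            "sex",
            "race_ethnicity",
            "age_group",
            "bmi_category",
            "bmi_mean",
            "n_valid_weeks",
        ]
    ]
    return ProcessResult(adherence=adherence, participants=participants, attrition=attrition)


# -- statistics tables ----------------------------------------------------


def build_group_summaries(
    result: ProcessResult, config: PipelineConfig, method: str = "step"
) -> pd.DataFrame:
    frame = result.method_frame(method)
    rows = []
    for factor in FACTORS:
        for summary in st.group_adherence_table(frame, "meets_2018", factor, config):
            rows.append(dataclasses.asdict(summary))
    return pd.DataFrame(rows)


def build_model_fits(
    result: ProcessResult, config: PipelineConfig, method: str = "step"
) -> pd.DataFrame:
    """Univariate fit per factor plus one multivariate fit, stacked."""
    frame = result.method_frame(method)
    frame = frame.assign(meets_2018=frame["meets_2018"].astype(bool))
    fits = []
    for factor in FACTORS:
        if frame[factor].nunique() < 2 or REFERENCES[factor] not in set(frame[factor]):
            continue
        fit = st.fit_logistic(
            frame, "meets_2018", [factor], REFERENCES, config, mode="univariate"
        )
        fits.append(fit)
    usable = [
        f
        for f in FACTORS
        if frame[f].nunique() >= 2 and REFERENCES[f] in set(frame[f])
    ]
    if len(usable) >= 2:
        fits.append(
            st.fit_logistic(
                frame, "meets_2018", usable, REFERENCES, config, mode="multivariate"
            )
        )
    out = []
    for fit in fits:
        terms = fit.terms.copy()
        terms.insert(0, "mode", fit.mode)
        terms["converged"] = fit.converged
        terms["max_vif"] = max(fit.vif.values()) if fit.vif else float("nan")
        terms["vif_ok"] = fit.vif_ok
        out.append(terms)
    if not out:
        return pd.DataFrame(
            columns=[
                "mode", "factor", "level", "reference_level", "beta", "se",
                "odds_ratio", "ci_low", "ci_high", "wald_p", "converged",
                "max_vif", "vif_ok",
            ]
        )
    return pd.concat(out, ignore_index=True)


def build_method_comparison(
    result: ProcessResult, config: PipelineConfig, outcome: str = "meets_2008"
) -> pd.DataFrame:
    """Paired McNemar tests between every pair of algorithms."""
    wide = result.adherence.pivot(
        index="person_id", columns="method", values=outcome
    ).astype(bool)
    rows = []
    pairs = [("device", "hr"), ("device", "step"), ("hr", "step")]
    for a, b in pairs:
        res = st.mcnemar_compare_methods(wide[a].to_numpy(), wide[b].to_numpy(), config)
        rows.append(
            {
                "outcome": outcome,
                "method_a": a,
                "method_b": b,
                "n_adherent_a": int(wide[a].sum()),
                "n_adherent_b": int(wide[b].sum()),
                **res,
            }
        )
    return pd.DataFrame(rows)


def _apply_suppression(summaries: pd.DataFrame) -> pd.DataFrame:
    """Replace displayed cells of suppressed rows with the literal token."""
    out = summaries.copy()
    numeric = ["n_adherent", "proportion", "wald_se", "wald_ci_low", "wald_ci_high"]
    out[numeric] = out[numeric].astype(object)
    mask = out["suppressed"].astype(bool)
    for col in numeric:
        out.loc[mask, col] = SUPPRESSED_TOKEN
    return out


def run_pipeline(
    minute_path,
    demo_path,
    config: PipelineConfig,
    out_dir,
    bmi_path=None,
) -> Dict[str, Path]:
    """Read inputs, process the cohort, and write every output table.

    Outputs: adherence.csv (participant x method), participants.csv,
    group_summaries.csv (suppression tokens applied), model_fits.csv,
    method_comparison.csv and manifest.json.  Runs with identical inputs,
    config and seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    minutes, report = read_minute_data(minute_path, config)
    demographics = read_demographics(demo_path, bmi_path)
    result = process_cohort(minutes, demographics, config, report)

    summaries = build_group_summaries(result, config)
    fits = build_model_fits(result, config)
    comparison = build_method_comparison(result, config)

    paths = {
        "adherence": out / "adherence.csv",
        "participants": out / "participants.csv",
        "group_summaries": out / "group_summaries.csv",
        "model_fits": out / "model_fits.csv",
        "method_comparison": out / "method_comparison.csv",
        "manifest": out / "manifest.json",
    }
    result.adherence.to_csv(paths["adherence"], index=False)
    result.participants.to_csv(paths["participants"], index=False)
    _apply_suppression(summaries).to_csv(paths["group_summaries"], index=False)
    fits.to_csv(paths["model_fits"], index=False)
    comparison.to_csv(paths["method_comparison"], index=False)

    manifest = {
        "config": config.to_dict(),
        "seed": config.random_seed,
        "attrition": result.attrition,
        "parse_report": report.to_dict(),
        "outputs": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
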