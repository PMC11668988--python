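"""Synthetic minute-level wearable cohorts with known ground truth.

Participants are drawn from a demographic mix, assigned an activity
archetype (optionally via a logistic adherence model over demographic
levels), and emitted as the exact CSV dialects the readers ingest.  Ground
truth — archetype, analytic weekly MVPA, and adherence flags — is computed
from the generating process, never by running the pipeline, so pipeline
runs can be validated against it without circularity.

Signal model per worn day: a contiguous wear block of minutes carries a low
background cadence; archetype-specific active runs (and/or scattered
isolated active minutes) are overlaid at higher cadence.  Heart rate is a
logistic link of (optionally exponentially smoothed) cadence times the
age-predicted maximum, plus optional Gaussian noise; the smoothing carry-over
makes the heart-rate algorithm systematically more generous than the cadence
algorithm, and an optional device-label "halo" around runs inflates the
device algorithm further, reproducing the device > HR > step ordering of
bouted-adherence estimates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "Archetype",
    "AdherenceModel",
    "CohortSpec",
    "SimulatedCohort",
    "DEFAULT_ARCHETYPES",
    "PUBLISHED_GROUP_COUNTS",
    "generate_cohort",
    "write_cohort",
    "simulate_outcomes",
    "generate_worked_examples",
]


# Adherent/total participant counts by demographic group, as printed by a
# large published US wearable cohort; used as worked-example inputs for the
# 2x2 odds-ratio routines.  The first level of each factor is the reference.
PUBLISHED_GROUP_COUNTS: Dict[str, Dict] = {
    "sex": {
        "reference": "male",
        "levels": {
            "male": (1069, 4007),
            "female": (1864, 9553),
            "other_or_not_specified": (73, 387),
        },
    },
    "race_ethnicity": {
        "reference": "nh_white",
        "levels": {
            "nh_white": (2454, 11109),
            "hispanic": (60, 310),
            "nh_asian_pi": (135, 430),
            "nh_black": (87, 684),
            "two_or_more": (61, 293),
            "other_or_not_specified": (209, 1121),
        },
    },
    "bmi_category": {
        "reference": "normal",
        "levels": {
            "normal": (727, 1994),
            "overweight": (598, 2487),
            "obese": (224, 1501),
            "severely_obese": (88, 1375),
            "other_or_not_specified": (1369, 6590),
        },
    },
    "age_group": {
        "reference": "18-29",
        "levels": {
            "18-29": (389, 1511),
            "30-39": (446, 2528),
            "40-49": (426, 2259),
            "50-59": (583, 2760),
            "60-69": (773, 3102),
            "70+": (389, 1787),
        },
    },
}


@dataclass(frozen=True)
class Archetype:
    """Daily activity structure for one participant type.

    ``runs_per_day`` contiguous active runs of ``run_minutes`` at
    ``run_cadence`` steps/min; ``scattered_active_minutes`` isolated active
    minutes placed on a 5-minute lattice (never forming a qualifying bout);
    everything else idles at ``background_cadence``.
    """

    name: str
    runs_per_day: int = 0
    run_minutes: int = 0
    run_cadence: float = 110.0
    run_cadence_sigma: float = 0.0  # lognormal sigma on the log scale
    scattered_active_minutes: int = 0
    scattered_cadence: float = 105.0
    background_cadence: float = 5.0  # Poisson mean steps/min outside activity


DEFAULT_ARCHETYPES: Dict[str, Archetype] = {
    "sedentary": Archetype("sedentary"),
    # 2 x 8 min walks: weekly weighted MVPA 112 < 150, and runs too short to bout
    "commuter": Archetype("commuter", runs_per_day=2, run_minutes=8, run_cadence=108.0),
    # 1 x 40 min run: weekly weighted MVPA 280 >= 150 with qualifying bouts
    "bout_exerciser": Archetype(
        "bout_exerciser", runs_per_day=1, run_minutes=40, run_cadence=112.0
    ),
    # isolated minutes only: unbouted MVPA 126/week, bouted 0
    "sporadic_mover": Archetype(
        "sporadic_mover", scattered_active_minutes=18, scattered_cadence=105.0
    ),
    # 30 min/day at 95 steps/min: below the cadence moderate threshold but in
    # the moderate %HRmax zone, so the HR algorithm counts what steps do not
    "brisk_walker": Archetype(
        "brisk_walker", runs_per_day=1, run_minutes=30, run_cadence=95.0
    ),
}


@dataclass(frozen=True)
class AdherenceModel:
    """Logistic model for who gets the adherent archetype.

    log-odds(adherent) = base_log_odds + sum of the participant's level
    effects; adherent draws receive ``adherent_archetype``, the rest are
    sampled from the cohort's (non-adherent) archetype mix.
    """

    base_log_odds: float = 0.0
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    adherent_archetype: str = "bout_exerciser"


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_participants: int = 50
    start_date: dt.date = dt.date(2021, 1, 1)
    n_days: int = 21
    seed: int = 0
    sex_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "male": 0.29,
            "female": 0.68,
            "other_or_not_specified": 0.03,
        }
    )
    race_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "nh_white": 0.80,
            "nh_black": 0.05,
            "nh_asian_pi": 0.03,
            "hispanic": 0.02,
            "two_or_more": 0.02,
            "other_or_not_specified": 0.08,
        }
    )
    age_low: int = 18
    age_high: int = 79
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "sedentary": 0.40,
            "commuter": 0.35,
            "sporadic_mover": 0.25,
        }
    )
    archetypes: Mapping[str, Archetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    adherence_model: Optional[AdherenceModel] = None
    # wear model
    wear_probability: float = 1.0  # per-day probability the device is worn
    wear_start_minute: int = 360  # 06:00
    wear_end_minute: int = 1320  # 22:00
    hr_missing_rate: float = 0.0
    run_jitter: bool = False  # randomise run placement and counts
    # heart-rate link: fraction of max HR = rest + gain * sigmoid((c - mid)/scale)
    hr_frac_rest: float = 0.48
    hr_frac_gain: float = 0.30
    hr_cadence_mid: float = 80.0
    hr_cadence_scale: float = 15.0
    hr_noise_sd: float = 0.0  # Gaussian noise on the HR fraction
    hr_carryover: float = 0.0  # EMA coefficient; >0 lets HR lag behind cadence
    # device-label inflation: minutes within this halo of a run are labelled
    # at least fairly_active, emulating proprietary over-counting
    device_halo_minutes: int = 0
    # BMI model
    bmi_mean: float = 29.0
    bmi_sd: float = 6.0
    bmi_missing_prob: float = 0.3
    bmi_max_measurements: int = 3

    def _validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if self.wear_probability <= 0:
            raise ValueError("wear probability must be positive (cohort would be empty)")
        for name, mix in (
            ("sex_mix", self.sex_mix),
            ("race_mix", self.race_mix),
            ("archetype_mix", self.archetype_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if not 0 <= self.hr_carryover < 1:
            raise ValueError("hr_carryover must lie in [0, 1)")
        if not self.wear_start_minute < self.wear_end_minute:
            raise ValueError("wear window must be non-empty")
        unknown = set(self.archetype_mix) - set(self.archetypes)
        if unknown:
            raise ValueError(f"archetype_mix references unknown archetypes {unknown}")
        if self.adherence_model is not None:
            if self.adherence_model.adherent_archetype not in self.archetypes:
                raise ValueError("adherent_archetype not defined in archetypes")


@dataclass
class SimulatedCohort:
    demographics: pd.DataFrame
    bmi: pd.DataFrame
    minutes: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


# -- analytic ground truth ------------------------------------------------


def _cadence_weight(cadence: float, config: PipelineConfig) -> float:
    """Weighted-MVPA contribution of one minute at a given cadence."""
    _, moderate, vigorous = config.step_thresholds
    if cadence >= vigorous:
        return config.vpa_weight
    if cadence >= moderate:
        return 1.0
    return 0.0


def _archetype_truth(
    archetype: Archetype, config: PipelineConfig
) -> Tuple[float, float, bool, bool]:
    """(weekly MVPA, weekly bouted MVPA, meets_2018, meets_2008), analytically.

    Uses the archetype's mean daily structure; noise-free specs realise these
    values exactly.
    """
    run_weight = _cadence_weight(archetype.run_cadence, config)
    scattered_weight = _cadence_weight(archetype.scattered_cadence, config)
    daily = (
        archetype.runs_per_day * archetype.run_minutes * run_weight
        + archetype.scattered_active_minutes * scattered_weight
    )
    bouted_daily = (
        archetype.runs_per_day * archetype.run_minutes * run_weight
        if archetype.run_minutes >= config.bout_min_duration
        else 0.0
    )
    weekly = 7.0 * daily
    bouted_weekly = 7.0 * bouted_daily
    return (
        weekly,
        bouted_weekly,
        weekly >= config.mvpa_target,
        bouted_weekly >= config.mvpa_target,
    )


# -- generation -----------------------------------------------------------


def _sample_level(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    levels = list(mix.keys())
    probs = np.array([mix[l] for l in levels], dtype=float)
    return levels[rng.choice(len(levels), p=probs / probs.sum())]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_day(
    rng: np.random.Generator,
    spec: CohortSpec,
    archetype: Archetype,
    max_hr: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One worn day: (minute_of_day, steps, heart_rate, device_label codes)."""
    start, end = spec.wear_start_minute, spec.wear_end_minute
    n = end - start
    minute_of_day = np.arange(start, end)
    cadence = rng.poisson(archetype.background_cadence, size=n).astype(float)
    run_mask = np.zeros(n, dtype=bool)

    # active runs
    if archetype.runs_per_day > 0 and archetype.run_minutes > 0:
        n_runs = (
            int(rng.poisson(archetype.runs_per_day))
            if spec.run_jitter
            else archetype.runs_per_day
        )
        for r in range(n_runs):
            length = archetype.run_minutes
            if spec.run_jitter:
                length = max(1, int(rng.geometric(1.0 / archetype.run_minutes)))
            if spec.run_jitter:
                offset = int(rng.integers(0, max(1, n - length)))
            else:
                offset = (r + 1) * n // (max(n_runs, 1) + 1)
            lo, hi = offset, min(offset + length, n)
            run_mask[lo:hi] = True
            if archetype.run_cadence_sigma > 0:
                cadence[lo:hi] = archetype.run_cadence * np.exp(
                    rng.normal(0.0, archetype.run_cadence_sigma, size=hi - lo)
                )
            else:
                cadence[lo:hi] = archetype.run_cadence

    # scattered isolated active minutes on a 5-minute lattice
    if archetype.scattered_active_minutes > 0:
        phase = int(rng.integers(0, 5)) if spec.run_jitter else 0
        positions = np.arange(phase, n, 5)[: archetype.scattered_active_minutes]
        cadence[positions] = archetype.scattered_cadence

    # heart rate from (smoothed) cadence through the logistic link
    if spec.hr_carryover > 0:
        smoothed = np.empty(n)
        state = cadence[0]
        alpha = spec.hr_carryover
        for i in range(n):
            state = alpha * state + (1.0 - alpha) * cadence[i]
            smoothed[i] = state
    else:
        smoothed = cadence
    frac = spec.hr_frac_rest + spec.hr_frac_gain * _sigmoid(
        (smoothed - spec.hr_cadence_mid) / spec.hr_cadence_scale
    )
    if spec.hr_noise_sd > 0:
        frac = frac + rng.normal(0.0, spec.hr_noise_sd, size=n)
    heart_rate = np.maximum(30.0, frac * max_hr)
    if spec.hr_missing_rate > 0:
        heart_rate = np.where(
            rng.random(n) < spec.hr_missing_rate, np.nan, heart_rate
        )

    # device labels: intensity of the cadence signal, optionally inflated by
    # a halo of fairly_active minutes around each run
    device = np.zeros(n, dtype=np.int8)
    device[cadence >= 60] = 1
    device[cadence >= 100] = 2
    device[cadence >= 130] = 3
    if spec.device_halo_minutes > 0 and run_mask.any():
        halo = run_mask.copy()
        w = spec.device_halo_minutes
        idx = np.flatnonzero(run_mask)
        for i in idx:
            halo[max(0, i - w) : min(n, i + w + 1)] = True
        device = np.maximum(device, np.where(halo, 2, 0).astype(np.int8))
    return minute_of_day, np.round(cadence), heart_rate, device


_DEVICE_NAMES = np.array(
    ["sedentary", "lightly_active", "fairly_active", "very_active"]
)


def generate_cohort(
    spec: CohortSpec, config: Optional[PipelineConfig] = None
) -> SimulatedCohort:
    """Generate a full cohort: demographics, BMI, minute data, ground truth.

    The seed fully determines every output.  Ground-truth adherence flags
    come from the archetype's analytic weekly MVPA (and the adherence-model
    draw when one is configured), not from the processing pipeline.
    """
    spec._validate()
    config = config or PipelineConfig()
    rng = np.random.default_rng(spec.seed)

    demo_rows = []
    bmi_rows = []
    truth_rows = []
    minute_frames: List[pd.DataFrame] = []

    for index in range(spec.n_participants):
        pid = f"P{index + 1:05d}"
        sex = _sample_level(rng, spec.sex_mix)
        race = _sample_level(rng, spec.race_mix)
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
        # birthday placed so the participant stays `age` for >= ~1 month
        offset_days = int(rng.integers(35, 330))
        birth_date = dt.date(
            spec.start_date.year - age, spec.start_date.month, 1
        ) - dt.timedelta(days=offset_days)

        if spec.adherence_model is not None:
            model = spec.adherence_model
            logit = model.base_log_odds
            for factor, level in (("sex", sex), ("race_ethnicity", race)):
                logit += model.effects.get(factor, {}).get(level, 0.0)
            adherent_draw = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            if adherent_draw:
                archetype_name = model.adherent_archetype
            else:
                archetype_name = _sample_level(rng, spec.archetype_mix)
        else:
            adherent_draw = None
            archetype_name = _sample_level(rng, spec.archetype_mix)
        archetype = spec.archetypes[archetype_name]

        weekly, bouted_weekly, meets_2018, meets_2008 = _archetype_truth(
            archetype, config
        )
        max_hr = config.max_hr_intercept - config.max_hr_slope * age

        # minute records
        day_frames = []
        for d in range(spec.n_days):
            if rng.random() >= spec.wear_probability:
                continue
            day = spec.start_date + dt.timedelta(days=d)
            mod, steps, hr, device = _simulate_day(rng, spec, archetype, max_hr)
            stamps = (
                pd.Timestamp(day)
                + pd.to_timedelta(mod, unit="m")
            )
            day_frames.append(
                pd.DataFrame(
                    {
                        "person_id": pid,
                        "datetime": stamps,
                        "steps": steps.astype(int),
                        "heart_rate": np.round(hr, 1),
                        "device_label": _DEVICE_NAMES[device],
                    }
                )
            )
        if day_frames:
            minute_frames.append(pd.concat(day_frames, ignore_index=True))

        # BMI measurements
        if rng.random() >= spec.bmi_missing_prob:
            true_bmi = float(np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd), 16, 60))
            n_meas = int(rng.integers(1, spec.bmi_max_measurements + 1))
            for _ in range(n_meas):
                day = spec.start_date + dt.timedelta(
                    days=int(rng.integers(0, spec.n_days))
                )
                bmi_rows.append(
                    {
                        "person_id": pid,
                        "bmi_date": day.isoformat(),
                        "bmi_value": round(true_bmi + float(rng.normal(0, 0.4)), 1),
                    }
                )

        demo_rows.append(
            {
                "person_id": pid,
                "sex": sex,
                "race_ethnicity": race,
                "birth_date": birth_date.isoformat(),
            }
        )
        truth_rows.append(
            {
                "person_id": pid,
                "archetype": archetype_name,
                "age_at_start": age,
                "adherent_draw": adherent_draw,
                "true_weekly_mvpa": weekly,
                "true_weekly_bouted_mvpa": bouted_weekly,
                "true_meets_2018": meets_2018,
                "true_meets_2008": meets_2008,
            }
        )

    minutes = (
        pd.concat(minute_frames, ignore_index=True)
        if minute_frames
        else pd.DataFrame(
            columns=["person_id", "datetime", "steps", "heart_rate", "device_label"]
        )
    )
    return SimulatedCohort(
        demographics=pd.DataFrame(demo_rows),
        bmi=pd.DataFrame(bmi_rows, columns=["person_id", "bmi_date", "bmi_value"]),
        minutes=minutes,
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> Dict[str, Path]:
    """Write the cohort as the CSV dialects the readers ingest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "minutes": out / "minutes.csv",
        "demographics": out / "demographics.csv",
        "bmi": out / "bmi.csv",
        "truth": out / "truth.csv",
    }
    minutes = cohort.minutes.copy()
    minutes["datetime"] = minutes["datetime"].dt.strftime("%Y-%m-%dT%H:%M")
    minutes.to_csv(paths["minutes"], index=False)
    cohort.demographics.to_csv(paths["demographics"], index=False)
    cohort.bmi.to_csv(paths["bmi"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths


# -- outcome-level simulation (for statistical recovery studies) ----------


def simulate_outcomes(
    n: int,
    model: AdherenceModel,
    mixes: Mapping[str, Mapping[str, float]],
    seed: int,
) -> pd.DataFrame:
    """Draw per-participant factor levels and a Bernoulli adherence outcome.

    The outcome's log-odds are ``model.base_log_odds`` plus the participant's
    per-level effects — the direct analogue of the cohort generator's
    adherence draw, at negligible cost, for parameter-recovery and null-
    calibration studies.
    """
    rng = np.random.default_rng(seed)
    columns: Dict[str, np.ndarray] = {}
    logit = np.full(n, model.base_log_odds, dtype=float)
    for factor, mix in mixes.items():
        levels = list(mix.keys())
        probs = np.array([mix[l] for l in levels], dtype=float)
        draws = rng.choice(len(levels), size=n, p=probs / probs.sum())
        values = np.array(levels, dtype=object)[draws]
        columns[factor] = values
        effects = model.effects.get(factor, {})
        if effects:
            shift = np.array([effects.get(l, 0.0) for l in levels])
            logit += shift[draws]
    outcome = rng.random(n) < _sigmoid(logit)
    frame = pd.DataFrame(columns)
    frame.insert(0, "person_id", [f"P{i + 1:05d}" for i in range(n)])
    frame["outcome"] = outcome
    return frame


# -- worked-example fixtures ---------------------------------------------


def generate_worked_examples(out_dir) -> Dict[str, Path]:
    """Write the small deterministic fixtures used in module examples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    counts_path = out / "group_2x2_counts.json"
    with open(counts_path, "w", encoding="utf-8") as fh:
        json.dump(PUBLISHED_GROUP_COUNTS, fh, indent=2, sort_keys=True)
    paths["group_2x2_counts"] = counts_path

    bout_patterns = {
        "ten_active": "A" * 10,
        "nine_active": "A" * 9,
        "split_within_budget": "A" * 5 + "I" * 2 + "A" * 5,
        "split_over_budget": "A" * 5 + "I" * 3 + "A" * 5,
    }
    bout_path = out / "bout_patterns.json"
    with open(bout_path, "w", encoding="utf-8") as fh:
        json.dump(bout_patterns, fh, indent=2, sort_keys=True)
    paths["bout_patterns"] = bout_path

    # one day with exactly 599 HR-bearing minutes and ample steps: invalid day
    rows = []
    day = dt.date(2021, 3, 1)
    for i in range(599):
        stamp = dt.datetime.combine(day, dt.time(5, 0)) + dt.timedelta(minutes=i)
        rows.append(
            {
                "person_id": "BOUNDARY",
                "datetime": stamp.strftime("%Y-%m-%dT%H:%M"),
                "steps": 20,
                "heart_rate": 70.0,
                "device_label": "sedentary",
            }
        )
    boundary_path = out / "boundary_day.csv"
    pd.DataFrame(rows).to_csv(boundary_path, index=False)
    paths["boundary_day"] = boundary_path
    return paths
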