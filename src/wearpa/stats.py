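"""Demographic classification rules and cohort-level statistics.

Covers: adult-record filtering, age-group assignment (most-valid-weeks rule),
BMI averaging with outlier removal, grouped adherence proportions with Wald
confidence intervals and small-cell suppression, 2x2 odds ratios, univariate
and multivariate logistic regression with VIF screening, pairwise chi-square
tests, and paired McNemar comparisons between algorithms.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import PipelineConfig
from .timeutil import add_years, completed_years
from .wear import WearCalendar, week_start_date

__all__ = [
    "AGE_GROUPS",
    "BMI_CATEGORIES",
    "Z_95",
    "filter_adult_minutes",
    "age_group_of",
    "assign_age_group",
    "classify_bmi",
    "GroupSummary",
    "group_adherence_table",
    "OddsRatioResult",
    "odds_ratio_from_counts",
    "ModelFit",
    "fit_logistic",
    "pairwise_chisq",
    "mcnemar_compare_methods",
]

AGE_GROUPS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+")
BMI_CATEGORIES = (
    "normal",
    "overweight",
    "obese",
    "severely_obese",
    "other_or_not_specified",
)

Z_95 = 1.96  # normal quantile used for all 95% Wald intervals


# -- demographic rules ----------------------------------------------------


def filter_adult_minutes(minutes: pd.DataFrame, birth_date: dt.date) -> pd.DataFrame:
    """Drop every record dated before the participant's 18th birthday."""
    if minutes.empty:
        return minutes.copy()
    cutoff = pd.Timestamp(add_years(birth_date, 18))
    return minutes.loc[minutes["datetime"] >= cutoff].reset_index(drop=True)


def age_group_of(age_years: int) -> str:
    """Decade-style age group for an adult age in completed years."""
    if age_years < 18:
        raise ValueError(f"age must be >= 18, got {age_years}")
    if age_years < 30:
        return "18-29"
    if age_years >= 70:
        return "70+"
    decade = (age_years // 10) * 10
    return f"{decade}-{decade + 9}"


def assign_age_group(
    birth_date: dt.date,
    valid_weeks: Iterable[Tuple[int, int]],
    config: PipelineConfig,
) -> Tuple[str, List[Tuple[int, int]]]:
    """Pick the age group holding the most valid weeks; drop the rest.

    Each valid week belongs to the age group of the participant's completed
    age on the week's first day.  Ties go to the older group.  Returns the
    chosen group and the (sorted) valid weeks retained for all downstream
    computation.
    """
    weeks = sorted(valid_weeks)
    if not weeks:
        raise ValueError("age-group assignment requires at least one valid week")
    by_group: Dict[str, List[Tuple[int, int]]] = {}
    for year, week in weeks:
        age = completed_years(birth_date, week_start_date(year, week))
        by_group.setdefault(age_group_of(age), []).append((year, week))
    chosen = max(
        by_group, key=lambda g: (len(by_group[g]), AGE_GROUPS.index(g))
    )
    return chosen, sorted(by_group[chosen])


def classify_bmi(
    measurements: Sequence[Tuple[dt.date, float]],
    first_valid_day: dt.date,
    last_valid_day: dt.date,
    config: PipelineConfig,
) -> Tuple[str, float]:
    """Average in-window BMI measurements and categorise the mean.

    Measurements outside [first_valid_day, last_valid_day] or beyond the
    outlier bounds are discarded.  Category edges are half-open upward:
    exactly 25.0 is overweight, exactly 35.0 severely obese.  Means below
    the underweight cutoff, or an empty remainder, fall into
    ``other_or_not_specified`` (the mean is NaN when nothing survives).
    """
    kept = [
        value
        for day, value in measurements
        if first_valid_day <= day <= last_valid_day
        and config.bmi_lower_outlier < value < config.bmi_upper_outlier
    ]
    if not kept:
        return "other_or_not_specified", float("nan")
    mean = float(np.mean(kept))
    if mean < config.bmi_underweight_cutoff:
        return "other_or_not_specified", mean
    if mean < 25.0:
        return "normal", mean
    if mean < 30.0:
        return "overweight", mean
    if mean < 35.0:
        return "obese", mean
    return "severely_obese", mean


# -- grouped proportions --------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    factor: str
    level: str
    n_participants: int
    n_adherent: int
    proportion: float
    wald_se: float
    wald_ci_low: float
    wald_ci_high: float
    suppressed: bool


def _wald_interval(p: float, n: int) -> Tuple[float, float, float]:
    se = math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")
    return se, max(0.0, p - Z_95 * se), min(1.0, p + Z_95 * se)


def group_adherence_table(
    participants: pd.DataFrame,
    outcome: str,
    factor: str,
    config: PipelineConfig,
    levels: Optional[Sequence[str]] = None,
) -> List[GroupSummary]:
    """One row per factor level: adherent count, proportion, Wald CI.

    Suppression is a display policy only: a level is flagged when either
    displayed cell (adherent or non-adherent count) falls below the
    suppression threshold, but the numbers are still computed and returned.
    """
    if levels is None:
        levels = sorted(participants[factor].dropna().unique())
    rows: List[GroupSummary] = []
    for level in levels:
        sub = participants.loc[participants[factor] == level]
        n = len(sub)
        adherent = int(sub[outcome].sum())
        if n == 0:
            rows.append(
                GroupSummary(factor, level, 0, 0, float("nan"), float("nan"),
                             float("nan"), float("nan"), True)
            )
            continue
        p = adherent / n
        se, lo, hi = _wald_interval(p, n)
        suppressed = (
            adherent < config.suppression_threshold
            or (n - adherent) < config.suppression_threshold
        )
        rows.append(GroupSummary(factor, level, n, adherent, p, se, lo, hi, suppressed))
    return rows


# -- odds ratios ----------------------------------------------------------


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    defined: bool


def odds_ratio_from_counts(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Cross-product odds ratio from a 2x2 table with 95% Wald CI.

    ``a``/``b`` are exposed adherent/non-adherent counts, ``c``/``d`` the
    reference group's.  A zero cell leaves the ratio undefined (flagged, no
    continuity correction applied).
    """
    for name, value in zip("abcd", (a, b, c, d)):
        if value < 0:
            raise ValueError(f"count {name} must be non-negative, got {value}")
    if min(a, b, c, d) == 0:
        nan = float("nan")
        return OddsRatioResult(nan, nan, nan, nan, nan, defined=False)
    oratio = (a * d) / (b * c)
    log_or = math.log(oratio)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=oratio,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        log_or=log_or,
        se_log_or=se,
        defined=True,
    )


# -- logistic regression --------------------------------------------------


@dataclass
class ModelFit:
    outcome: str
    mode: str  # "univariate" | "multivariate"
    terms: pd.DataFrame  # factor, level, reference_level, beta, se, odds_ratio, ci_low, ci_high, wald_p
    vif: Dict[str, float]
    converged: bool
    vif_ok: bool = True
    n_obs: int = 0


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return float("inf")


def _design_matrix(
    data: pd.DataFrame,
    factors: Sequence[str],
    references: Mapping[str, str],
    levels: Optional[Mapping[str, Sequence[str]]] = None,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Dummy-coded design with an intercept; reference levels absorbed."""
    columns = {"const": np.ones(len(data))}
    term_index: List[Tuple[str, str]] = []
    for factor in factors:
        ref = references[factor]
        observed = list(pd.unique(data[factor]))
        if ref not in observed:
            raise ValueError(f"reference level {ref!r} absent from factor {factor!r}")
        if levels and factor in levels:
            ordered = [l for l in levels[factor] if l in observed]
        else:
            ordered = sorted(observed)
        for level in ordered:
            if level == ref:
                continue
            columns[f"{factor}[{level}]"] = (data[factor] == level).astype(float).to_numpy()
            term_index.append((factor, level))
    return pd.DataFrame(columns, index=data.index), term_index


def _vif_table(X: pd.DataFrame) -> Dict[str, float]:
    """VIF per non-intercept design column via auxiliary linear regressions."""
    predictors = [c for c in X.columns if c != "const"]
    vif: Dict[str, float] = {}
    for col in predictors:
        others = ["const"] + [c for c in predictors if c != col]
        y = X[col].to_numpy()
        A = X[others].to_numpy()
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vif[col] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        vif[col] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vif


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    references: Mapping[str, str],
    config: PipelineConfig,
    mode: str = "univariate",
    levels: Optional[Mapping[str, Sequence[str]]] = None,
    freq_weights: Optional[np.ndarray] = None,
) -> ModelFit:
    """Maximum-likelihood logistic fit with dummy coding and Wald inference.

    Returns per-term odds ratios, 95% Wald CIs and two-sided Wald p-values,
    plus a VIF per design column (flagging the fit when any VIF >= 5).
    Non-convergence or separation is reported via ``converged`` rather than
    silently falling back.
    """
    X, term_index = _design_matrix(data, factors, references, levels)
    y = data[outcome].astype(float).to_numpy()
    model = sm.GLM(
        y,
        X,
        family=sm.families.Binomial(),
        freq_weights=freq_weights,
    )
    converged = True
    try:
        result = model.fit(maxiter=200)
        converged = bool(result.converged)
    except Exception:
        result = None
        converged = False

    rows = []
    if result is not None:
        params = result.params
        bse = result.bse
        for factor, level in term_index:
            name = f"{factor}[{level}]"
            beta = float(params[name])
            se = float(bse[name])
            z = beta / se if se > 0 else float("nan")
            p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else float("nan")
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "reference_level": references[factor],
                    "beta": beta,
                    "se": se,
                    "odds_ratio": _safe_exp(beta),
                    "ci_low": _safe_exp(beta - Z_95 * se),
                    "ci_high": _safe_exp(beta + Z_95 * se),
                    "wald_p": p,
                }
            )
    terms = pd.DataFrame(
        rows,
        columns=[
            "factor",
            "level",
            "reference_level",
            "beta",
            "se",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "wald_p",
        ],
    )
    vif = _vif_table(X)
    vif_ok = all(v < 5.0 for v in vif.values()) if vif else True
    return ModelFit(
        outcome=outcome,
        mode=mode,
        terms=terms,
        vif=vif,
        converged=converged,
        vif_ok=vif_ok,
        n_obs=len(data),
    )


# -- pairwise tests -------------------------------------------------------


def pairwise_chisq(
    counts: Mapping[str, Tuple[int, int]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Pearson chi-square for every pair of levels.

    ``counts`` maps level -> (adherent, total).  Pairs with a zero margin
    are reported as skipped.  Significance is flagged at the
    Bonferroni-adjusted chi-square alpha; the continuity correction is off
    by default and switchable via config.
    """
    rows = []
    for (la, (adh_a, n_a)), (lb, (adh_b, n_b)) in itertools.combinations(
        sorted(counts.items()), 2
    ):
        table = np.array(
            [[adh_a, n_a - adh_a], [adh_b, n_b - adh_b]], dtype=float
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append(
                {
                    "level_a": la,
                    "level_b": lb,
                    "statistic": float("nan"),
                    "p_value": float("nan"),
                    "significant": False,
                    "skipped": True,
                }
            )
            continue
        stat, p, _, _ = sps.chi2_contingency(
            table, correction=config.continuity_correction
        )
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "statistic": float(stat),
                "p_value": float(p),
                "significant": bool(p < config.alpha_chisq),
                "skipped": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["level_a", "level_b", "statistic", "p_value", "significant", "skipped"],
    )


def mcnemar_compare_methods(
    flags_a: Sequence[bool],
    flags_b: Sequence[bool],
    config: PipelineConfig,
) -> dict:
    """Paired McNemar test on two algorithms' adherence flags.

    Uses the chi-square form (b - c)^2 / (b + c) on the discordant counts,
    referenced to a 1-df chi-square; no discordant pairs give statistic 0,
    p = 1.  Continuity correction is off by default.
    """
    fa = np.asarray(flags_a, dtype=bool)
    fb = np.asarray(flags_b, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError("paired flag vectors must have equal length")
    b = int(np.sum(fa & ~fb))
    c = int(np.sum(~fa & fb))
    if b + c == 0:
        stat, p = 0.0, 1.0
    else:
        diff = abs(b - c)
        if config.continuity_correction:
            diff = max(0.0, diff - 1.0)
        stat = diff**2 / (b + c)
        p = float(sps.chi2.sf(stat, df=1))
    return {
        "n_pairs": int(fa.size),
        "b_only_first": b,
        "c_only_second": c,
        "statistic": float(stat),
        "p_value": float(p),
        "significant": bool(p < config.alpha_mcnemar),
    }
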