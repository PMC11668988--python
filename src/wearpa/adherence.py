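"""Weekly MVPA, bout detection, and guideline adherence scoring.

Weighted MVPA counts each moderate minute once and each vigorous minute
``vpa_weight`` (default 2) times.  The 2018-style score averages all weighted
MVPA over valid weeks; the 2008-style score keeps only MVPA accrued inside
bouts of at least ``bout_min_duration`` minutes, where up to
``bout_max_interruption`` below-threshold minutes may be absorbed per bout.
Both scores call a participant adherent at a weekly average of
``mvpa_target`` minutes or more (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .intensity import CODE_MODERATE, CODE_VIGOROUS

__all__ = [
    "Bout",
    "AdherenceResult",
    "detect_bouts",
    "active_flags",
    "day_weighted_mvpa",
    "day_bouted_weighted_mvpa",
    "weekly_mvpa",
    "participant_adherence",
]


@dataclass(frozen=True)
class Bout:
    """One qualifying activity bout on a day's minute grid.

    ``start`` and ``end`` index the first and last minute (both active);
    interruption minutes are the absorbed inactive minutes between them.
    """

    start: int
    end: int
    active_minutes: int
    interruption_minutes: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AdherenceResult:
    participant_id: str
    method: str
    weekly_mvpa_2018: float  # mean weighted MVPA minutes/week over valid weeks
    weekly_bouted_mvpa_2008: float
    meets_2018: bool
    meets_2008: bool


def detect_bouts(flags: Sequence[bool], config: PipelineConfig) -> List[Bout]:
    """Greedy left-to-right bout detection on a per-minute activity sequence.

    A candidate bout opens at the earliest unconsumed active minute and is
    extended as far right as possible: inactive minutes are absorbed while
    the bout's cumulative interruption budget allows, and the bout closes at
    the last active minute reached.  The candidate is kept when its span
    reaches the minimum duration; otherwise the scan retries from the next
    active minute.  Kept bouts never overlap and consume their span.
    """
    min_span = config.bout_min_duration
    budget = config.bout_max_interruption
    n = len(flags)
    bouts: List[Bout] = []
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        # extend: absorb inactive minutes while cumulative interruptions fit
        interruptions = 0
        pending = 0
        last_active = i
        k = i + 1
        while k < n:
            if flags[k]:
                interruptions += pending
                pending = 0
                last_active = k
            else:
                pending += 1
                if interruptions + pending > budget:
                    break
            k += 1
        span = last_active - i + 1
        if span >= min_span:
            bouts.append(
                Bout(
                    start=i,
                    end=last_active,
                    active_minutes=span - interruptions,
                    interruption_minutes=interruptions,
                )
            )
            i = last_active + 1
        else:
            i += 1
    return bouts


def active_flags(codes: np.ndarray) -> np.ndarray:
    """Above-threshold mask: moderate or vigorous minutes are active."""
    return (codes == CODE_MODERATE) | (codes == CODE_VIGOROUS)


def day_weighted_mvpa(codes: np.ndarray, config: PipelineConfig) -> float:
    """Weighted MVPA minutes in one day: moderate + vpa_weight * vigorous."""
    moderate = int(np.sum(codes == CODE_MODERATE))
    vigorous = int(np.sum(codes == CODE_VIGOROUS))
    return moderate + config.vpa_weight * vigorous


def day_bouted_weighted_mvpa(codes: np.ndarray, config: PipelineConfig) -> float:
    """Weighted MVPA accrued inside qualifying bouts on one day's grid.

    Interruption minutes lie below threshold and contribute nothing; the
    sleep-window excision and day boundaries bracket the grid, so adjacency
    never crosses them.
    """
    flags = active_flags(codes)
    total = 0.0
    for bout in detect_bouts(flags, config):
        segment = codes[bout.start : bout.end + 1]
        moderate = int(np.sum(segment == CODE_MODERATE))
        vigorous = int(np.sum(segment == CODE_VIGOROUS))
        total += moderate + config.vpa_weight * vigorous
    return total


def weekly_mvpa(daily_values: Sequence[float], config: PipelineConfig) -> float:
    """Combine per-valid-day weighted MVPA into a weekly figure.

    Under the default ``extrapolate`` scaling the valid-day mean is scaled to
    a 7-day equivalent (7 * sum / n_valid_days); ``raw_sum`` reports the
    plain sum over valid days.
    """
    if len(daily_values) == 0:
        raise ValueError("weekly MVPA requires at least one valid day")
    total = float(np.sum(daily_values))
    if config.weekly_scaling == "extrapolate":
        return 7.0 * total / len(daily_values)
    return total


def participant_adherence(
    participant_id: str,
    method: str,
    week_values: Dict[Tuple[int, int], Tuple[float, float]],
    config: PipelineConfig,
) -> AdherenceResult:
    """Score one participant x method from per-week (unbouted, bouted) MVPA.

    ``week_values`` maps each valid week to its weekly weighted MVPA under
    the 2018-style (all minutes) and 2008-style (bouted) definitions, as
    produced by :func:`weekly_mvpa`.  Scores are means over valid weeks;
    the adherence threshold is inclusive.
    """
    if not week_values:
        raise ValueError(
            f"participant {participant_id} has no valid weeks; exclude upstream"
        )
    unbouted = float(np.mean([v[0] for v in week_values.values()]))
    bouted = float(np.mean([v[1] for v in week_values.values()]))
    return AdherenceResult(
        participant_id=participant_id,
        method=method,
        weekly_mvpa_2018=unbouted,
        weekly_bouted_mvpa_2008=bouted,
        meets_2018=unbouted >= config.mvpa_target,
        meets_2008=bouted >= config.mvpa_target,
    )
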