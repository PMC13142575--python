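"""Observation spans, consecutive-period segmentation, entry times, filters.

The maximum observation span runs from a participant's first to last billing
code. Consecutive observation periods are maximal runs of codes in which
adjacent codes are separated by less than a gap threshold (default 548 days,
i.e. 1.5 years at 365.25 days/year, read strictly: a gap equal to the
threshold splits). The start of the most recent consecutive period serves as
an alternative entry time for left-truncation adjustment, alongside the first
billing code and no truncation (birth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

GAP_THRESHOLD_DAYS = 548  # ceil(1.5 * 365.25)

ENTRY_SCENARIOS = ("first_code", "recent_period_start", "no_truncation")


@dataclass
class ObservationSummary:
    participant_id: str
    first_code_age_days: int
    last_code_age_days: int
    max_observation_days: int
    periods: List[Tuple[int, int]]
    recent_period_start_days: int


def consecutive_periods(
    code_ages_days, gap_threshold_days: int = GAP_THRESHOLD_DAYS
) -> List[Tuple[int, int]]:
    """Segment sorted code ages into consecutive observation periods.

    Adjacent codes with a gap < ``gap_threshold_days`` share a period; a gap
    >= the threshold starts a new one. Each period spans its first to last
    code age (single-code periods have zero length).
    """
    ages = np.asarray(code_ages_days)
    if ages.size == 0:
        raise ValueError("participant has no billing codes (no EHR data)")
    if np.any(np.diff(ages) < 0):
        raise ValueError("code ages must be sorted ascending")
    breaks = np.flatnonzero(np.diff(ages) >= gap_threshold_days)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ages.size - 1]))
    return [(int(ages[s]), int(ages[e])) for s, e in zip(starts, ends)]


def summarize_participant(
    participant_id: str, code_ages_days, gap_threshold_days: int = GAP_THRESHOLD_DAYS
) -> ObservationSummary:
    periods = consecutive_periods(code_ages_days, gap_threshold_days)
    first = periods[0][0]
    last = periods[-1][1]
    return ObservationSummary(
        participant_id=participant_id,
        first_code_age_days=first,
        last_code_age_days=last,
        max_observation_days=last - first,
        periods=periods,
        recent_period_start_days=periods[-1][0],
    )


def summarize_observation(
    billing: pd.DataFrame, gap_threshold_days: int = GAP_THRESHOLD_DAYS
) -> pd.DataFrame:
    """Per-participant observation summary table for a whole billing stream."""
    if billing.empty:
        raise ValueError("billing table is empty (no EHR data)")
    df = billing[["participant_id", "age_days"]].sort_values(
        ["participant_id", "age_days"], kind="mergesort"
    )
    pid = df["participant_id"].to_numpy()
    age = df["age_days"].to_numpy()
    new_pid = np.concatenate(([True], pid[1:] != pid[:-1]))
    big_gap = np.concatenate(([False], np.diff(age) >= gap_threshold_days))
    new_period = new_pid | big_gap
    period_id = np.cumsum(new_period)
    g = pd.DataFrame({"participant_id": pid, "age_days": age, "period_id": period_id})
    per_period = g.groupby("period_id").agg(
        participant_id=("participant_id", "first"),
        start=("age_days", "first"),
        end=("age_days", "last"),
        n_codes=("age_days", "size"),
    )
    out = per_period.groupby("participant_id").agg(
        first_code_age_days=("start", "first"),
        last_code_age_days=("end", "last"),
        n_periods=("start", "size"),
        recent_period_start_days=("start", "last"),
    )
    out["max_observation_days"] = out["last_code_age_days"] - out["first_code_age_days"]
    return out.reset_index()


def entry_time(summary, scenario: str) -> int:
    """Entry age (days) under one of the three left-truncation scenarios."""
    if scenario not in ENTRY_SCENARIOS:
        raise ValueError(f"unknown entry scenario {scenario!r}; expected {ENTRY_SCENARIOS}")
    if scenario == "no_truncation":
        return 0
    if scenario == "first_code":
        return int(summary.first_code_age_days if hasattr(summary, "first_code_age_days")
                   else summary["first_code_age_days"])
    return int(summary.recent_period_start_days if hasattr(summary, "recent_period_start_days")
               else summary["recent_period_start_days"])


def apply_cohort_filters(
    participants: pd.DataFrame,
    summaries: pd.DataFrame,
    phenotypes: pd.DataFrame,
    min_observation_days: int = 365,
    min_adult_age_years: float = 18.0,
    min_onset_age_years: float = 17.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rules; return (kept merged table, exclusion log).

    Rules, checked in fixed order so the log is deterministic: at least
    ``min_observation_days`` of maximum EHR observation; adult at enrollment;
    no CHD onset before ``min_onset_age_years`` (pediatric-onset disease is
    out of scope). One reason is recorded per removed participant.
    """
    from .simulate import DAYS_PER_YEAR  # avoid cycle at import time

    merged = participants.merge(summaries, on="participant_id", how="inner").merge(
        phenotypes, on="participant_id", how="left"
    )
    merged["chd"] = merged["chd"].fillna(False).astype(bool)
    onset_years = merged["onset_age_days"] / DAYS_PER_YEAR

    short = merged["max_observation_days"] < min_observation_days
    minor = ~short & (merged["enrollment_age_years"] < min_adult_age_years)
    early = (
        ~short
        & ~minor
        & merged["chd"]
        & (onset_years < min_onset_age_years)
    )
    excluded = short | minor | early
    reason = np.select(
        [short, minor, early],
        ["short_observation", "under_adult_age", "early_onset"],
        default="",
    )
    exclusions = pd.DataFrame(
        {
            "participant_id": merged.loc[excluded, "participant_id"],
            "reason": reason[excluded.to_numpy()],
        }
    ).reset_index(drop=True)
    kept = merged.loc[~excluded].reset_index(drop=True)
    return kept, exclusions
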