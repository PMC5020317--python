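"""Per-volunteer engagement metrics.

A volunteer is *active* on a day if they made at least one observation
that day.  Four metrics summarise a volunteer's contribution pattern:

- ``n_observations`` — total records submitted;
- ``activity_ratio`` (AR) — active days divided by the days linked to
  the dataset (first to last active day, inclusive);
- ``relative_activity_duration`` (RAD) — active days divided by the
  length of the whole study window;
- ``variation_in_periodicity`` (VP) — the volunteer's mean gap between
  sequential active days divided by the cohort average of those mean
  gaps.  Volunteers active on a single day have no gaps and get VP = 0,
  flagged via ``single_day_flag``.

For every volunteer RAD <= AR (the linked period is contained in the
window), and the mean of VP over multi-day volunteers is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyWindow",
    "ActivityHistory",
    "build_histories",
    "activity_ratio",
    "relative_activity_duration",
    "variation_in_periodicity",
    "engagement_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "n_observations",
    "activity_ratio",
    "relative_activity_duration",
    "variation_in_periodicity",
]


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive study observation period."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("study window end precedes start")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days + 1

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "StudyWindow":
        dates = pd.to_datetime(records["date"])
        return cls(dates.min().normalize(), dates.max().normalize())


@dataclass
class ActivityHistory:
    """One volunteer's active days and record count."""

    recorder_id: str
    active_dates: np.ndarray  # sorted, unique, datetime64[D]
    n_observations: int

    @property
    def n_active_days(self) -> int:
        return len(self.active_dates)

    @property
    def linked_days(self) -> int:
        """Days between first and last active day, inclusive."""
        span = (self.active_dates[-1] - self.active_dates[0]).astype("timedelta64[D]")
        return int(span.astype(int)) + 1

    def mean_gap(self) -> float | None:
        """Mean days between sequential active days; None if single-day."""
        if self.n_active_days < 2:
            return None
        gaps = np.diff(self.active_dates).astype("timedelta64[D]").astype(float)
        return float(gaps.mean())


def build_histories(records: pd.DataFrame) -> list[ActivityHistory]:
    """Group cleaned records into one :class:`ActivityHistory` per volunteer.

    Records by group or anonymous recorders must be excluded upstream
    (``is_group``/``is_anonymous`` flags from ingestion).
    """
    if len(records) == 0:
        return []
    if "is_group" in records.columns and bool(records["is_group"].any()):
        raise ValueError("group-recorder records must be excluded before profiling")
    if "is_anonymous" in records.columns and bool(records["is_anonymous"].any()):
        raise ValueError("anonymous records must be excluded before profiling")
    out = []
    dates = pd.to_datetime(records["date"]).to_numpy().astype("datetime64[D]")
    df = pd.DataFrame({"recorder_id": records["recorder_id"].to_numpy(), "date": dates})
    for rid, sub in df.groupby("recorder_id", sort=True):
        active = np.unique(sub["date"].to_numpy())
        out.append(ActivityHistory(str(rid), active, int(len(sub))))
    return out


def activity_ratio(history: ActivityHistory) -> float:
    """Active days / linked days; 1.0 for single-day volunteers."""
    return history.n_active_days / history.linked_days


def relative_activity_duration(history: ActivityHistory, window: StudyWindow) -> float:
    """Active days / study-window length."""
    first = pd.Timestamp(history.active_dates[0])
    last = pd.Timestamp(history.active_dates[-1])
    if first < window.start or last > window.end:
        raise ValueError(
            f"recorder {history.recorder_id!r} has activity outside the study window"
        )
    return history.n_active_days / window.length_days


def variation_in_periodicity(histories: list[ActivityHistory]) -> dict[str, float]:
    """VP per volunteer: individual mean gap over the cohort mean of mean gaps.

    The denominator is the unweighted mean over volunteers with at least
    two active days of their individual mean gaps (so VP averages to 1
    over those volunteers).  Volunteers with a single active day have no
    gaps and receive VP = 0.
    """
    gaps = {h.recorder_id: h.mean_gap() for h in histories}
    multi = [g for g in gaps.values() if g is not None]
    if not multi:
        raise ValueError("no volunteer has two or more active days; VP undefined")
    cohort_mean = float(np.mean(multi))
    return {
        rid: (0.0 if g is None else g / cohort_mean) for rid, g in gaps.items()
    }


def engagement_table(
    records: pd.DataFrame, window: StudyWindow | None = None
) -> pd.DataFrame:
    """Compute all four engagement metrics for every volunteer.

    Parameters
    ----------
    records
        Cleaned records (one row per observation) for individual
        volunteers only.
    window
        Study observation period; defaults to the records' date span.

    Returns
    -------
    DataFrame indexed by ``recorder_id`` with columns ``n_observations,
    n_active_days, linked_days, activity_ratio,
    relative_activity_duration, variation_in_periodicity,
    single_day_flag``.
    """
    histories = build_histories(records)
    if not histories:
        return pd.DataFrame(
            columns=[
                "n_observations",
                "n_active_days",
                "linked_days",
                *METRIC_COLUMNS[1:],
                "single_day_flag",
            ],
            index=pd.Index([], name="recorder_id"),
        )
    if window is None:
        window = StudyWindow.from_records(records)
    try:
        vp = variation_in_periodicity(histories)
    except ValueError:
        vp = {h.recorder_id: 0.0 for h in histories}
    rows = {
        h.recorder_id: {
            "n_observations": h.n_observations,
            "n_active_days": h.n_active_days,
            "linked_days": h.linked_days,
            "activity_ratio": activity_ratio(h),
            "relative_activity_duration": relative_activity_duration(h, window),
            "variation_in_periodicity": vp[h.recorder_id],
            "single_day_flag": h.n_active_days == 1,
        }
        for h in histories
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "recorder_id"
    return table
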