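"""From per-minute counts to daily activity and intensity profiles.

The analysis scale is ln(1 + count) per minute, then the arithmetic mean in
each 5-minute interval (transform first, bin second — the order matters on
skewed counts).  Per subject, the 7 baseline daily curves are stratified into
weekdays (Mon-Fri) and weekends (Sat-Sun) and averaged within day type to
give the activity profiles Y_weekday(t), Y_weekend(t).  The intensity profile

    I(t) = Y(t) - Ave(Y)

subtracts the subject's scalar grand mean over all 7 daily curves, removing
cat- and accelerometer-specific level effects; positive intensity means "more
active than typical for this cat".  With complete 5 + 2 day data the weighted
mean (5 * mean_t I_weekday + 2 * mean_t I_weekend) / 7 is exactly zero.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BIN_MINUTES, DEFAULT_GRID, N_BINS, N_MINUTES_PER_DAY, TimeGrid
from .io import EpochSeries

WEEKDAY = "weekday"
WEEKEND = "weekend"


class PreprocessingError(ValueError):
    pass


@dataclass
class DailyCurve:
    """One day's 288-point log-scale activity curve with its day-type label."""

    values: np.ndarray
    daytype: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise PreprocessingError(f"curve must have {N_BINS} points")
        if not np.all(np.isfinite(self.values)):
            raise PreprocessingError("curve contains non-finite values")
        if self.daytype not in (WEEKDAY, WEEKEND):
            raise PreprocessingError(f"unknown daytype {self.daytype!r}")


@dataclass
class CatProfile:
    """A subject's day-type-averaged activity and intensity profiles.

    ``ave`` is the unweighted grand mean over all 7x288 daily-curve values;
    the intensity curves are the activity curves minus ``ave``.
    """

    cat_id: str
    Y_weekday: np.ndarray
    Y_weekend: np.ndarray
    ave: float

    @property
    def I_weekday(self) -> np.ndarray:
        return self.Y_weekday - self.ave

    @property
    def I_weekend(self) -> np.ndarray:
        return self.Y_weekend - self.ave

    def activity(self, daytype: str) -> np.ndarray:
        return self.Y_weekday if daytype == WEEKDAY else self.Y_weekend

    def intensity(self, daytype: str) -> np.ndarray:
        return self.I_weekday if daytype == WEEKDAY else self.I_weekend


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise ln(1 + x); order-preserving, 0 maps to 0."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise PreprocessingError("negative counts passed to log_transform")
    return np.log1p(counts)


def bin_five_minutes(values: np.ndarray) -> np.ndarray:
    """Mean over each left-closed 5-minute interval: 1440 values -> 288."""
    values = np.asarray(values, dtype=float)
    if values.shape != (N_MINUTES_PER_DAY,):
        raise PreprocessingError(
            f"expected {N_MINUTES_PER_DAY} per-minute values, got {values.shape}"
        )
    return values.reshape(N_BINS, BIN_MINUTES).mean(axis=1)


def split_daytype(date: _dt.date) -> str:
    """Saturday/Sunday -> weekend, Monday-Friday -> weekday."""
    return WEEKEND if date.weekday() >= 5 else WEEKDAY


def daily_curve(series: EpochSeries) -> DailyCurve:
    """Transform-then-bin one subject-day to its 288-point log-scale curve."""
    return DailyCurve(
        values=bin_five_minutes(log_transform(series.counts)),
        daytype=split_daytype(series.date),
    )


def select_baseline_days(series: list[EpochSeries]) -> list[EpochSeries]:
    """Select the 7 baseline days from a longer wear record.

    The first and last recorded days are deleted (partial collar wear), and
    the chronologically last 7 remaining complete days are returned.  Requires
    at least 9 recorded days.
    """
    if not series:
        raise PreprocessingError("no days recorded")
    cat_id = series[0].cat_id
    ordered = sorted(series, key=lambda s: s.date)
    if len(ordered) < 9:
        raise PreprocessingError(
            f"cat {cat_id}: need >= 9 recorded days to select a 7-day baseline, "
            f"got {len(ordered)}"
        )
    usable = ordered[1:-1]
    return usable[-7:]


def build_profile(curves: list[DailyCurve], cat_id: str) -> CatProfile:
    """Average 5 weekday and 2 weekend daily curves into a CatProfile."""
    wd = [c.values for c in curves if c.daytype == WEEKDAY]
    we = [c.values for c in curves if c.daytype == WEEKEND]
    if len(wd) != 5 or len(we) != 2:
        raise PreprocessingError(
            f"cat {cat_id}: need exactly 5 weekday and 2 weekend curves, "
            f"got {len(wd)} weekday / {len(we)} weekend"
        )
    Y_wd = np.mean(wd, axis=0)
    Y_we = np.mean(we, axis=0)
    ave = float(np.mean(np.vstack(wd + we)))
    return CatProfile(cat_id=cat_id, Y_weekday=Y_wd, Y_weekend=Y_we, ave=ave)


def profile_from_series(series: list[EpochSeries]) -> CatProfile:
    """Build a CatProfile straight from a subject's 7 baseline EpochSeries."""
    if not series:
        raise PreprocessingError("no series given")
    cat_id = series[0].cat_id
    if len(series) > 7:
        series = select_baseline_days(series)
    if len(series) != 7:
        raise PreprocessingError(f"cat {cat_id}: need 7 baseline days, got {len(series)}")
    return build_profile([daily_curve(s) for s in series], cat_id)


def group_mean_profiles(
    profiles: list[CatProfile], groups: dict[str, str]
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Pointwise mean activity and intensity per group x day type.

    ``groups`` maps cat_id -> group label.  Returns
    {(group, daytype): {"activity": curve, "intensity": curve}}.
    """
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    labels = sorted(set(groups.values()))
    for g in labels:
        members = [p for p in profiles if groups.get(p.cat_id) == g]
        if not members:
            raise PreprocessingError(f"empty group {g!r}")
        for daytype in (WEEKEND, WEEKDAY):
            out[(g, daytype)] = {
                "activity": np.mean([p.activity(daytype) for p in members], axis=0),
                "intensity": np.mean([p.intensity(daytype) for p in members], axis=0),
            }
    return out


def mean_preTransform_count(series: list[EpochSeries]) -> float:
    """A subject's average per-minute raw count over their baseline days."""
    if not series:
        raise PreprocessingError("no series given")
    return float(np.mean([s.counts.mean() for s in series]))


def cohort_summary(
    subject_means: dict[str, float], groups: dict[str, str]
) -> pd.DataFrame:
    """Five-number summary + mean of per-subject average per-minute counts.

    Quartiles use linear (type-7) interpolation; the convention is recorded
    in the output.
    """
    rows = []
    for g in sorted(set(groups.values())):
        vals = np.array(
            [m for cid, m in subject_means.items() if groups.get(cid) == g], dtype=float
        )
        if vals.size == 0:
            raise PreprocessingError(f"empty group {g!r}")
        rows.append(
            {
                "group": g,
                "n": int(vals.size),
                "minimum": vals.min(),
                "q1": np.quantile(vals, 0.25),  # type-7 linear interpolation
                "median": np.quantile(vals, 0.5),
                "mean": vals.mean(),
                "q3": np.quantile(vals, 0.75),
                "maximum": vals.max(),
                "quartile_method": "linear (type 7)",
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(
    profiles: list[CatProfile], grid: TimeGrid = DEFAULT_GRID
) -> pd.DataFrame:
    """Tidy long-format export: cat_id, daytype, bin_index, t_hours, activity, intensity."""
    t = grid.t
    frames = []
    for p in sorted(profiles, key=lambda p: p.cat_id):
        for daytype in (WEEKDAY, WEEKEND):
            frames.append(
                pd.DataFrame(
                    {
                        "cat_id": p.cat_id,
                        "daytype": daytype,
                        "bin_index": np.arange(grid.n_bins),
                        "t_hours": t,
                        "activity": p.activity(daytype),
                        "intensity": p.intensity(daytype),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
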