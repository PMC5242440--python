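"""Per-minute activity CSV and subject covariate table I/O.

The on-disk epoch format is one row per minute, long format:

    cat_id,date,time,count

with ISO-8601 dates, ``time`` as HH:MM local clock labels (no time-zone
arithmetic; minute 0 = 00:00), and non-negative integer counts.  A day is
usable only if all 1440 minutes are present exactly once; incomplete days are
dropped and reported, never silently repaired.

The covariate table is one row per cat:

    cat_id,group,study,age,bcs,sex,tpain,tdjd,max_single_joint_pain

``tpain`` is the total orthopedic pain score (sum of per-joint 0-4 scores,
possible range 0-80); ``tdjd`` the total radiographic DJD score (sum of
per-joint 0-10 scores, possible range 0-200); ``bcs`` the 9-point body
condition score.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import N_MINUTES_PER_DAY

EPOCH_COLUMNS = ["cat_id", "date", "time", "count"]
COVARIATE_COLUMNS = [
    "cat_id",
    "group",
    "study",
    "age",
    "bcs",
    "sex",
    "tpain",
    "tdjd",
    "max_single_joint_pain",
]


class EpochParseError(ValueError):
    """Raised on malformed epoch rows (negative/non-integer counts, duplicates)."""


class CovariateError(ValueError):
    """Raised on out-of-range or malformed covariate values."""


@dataclass
class EpochSeries:
    """One subject-day of 1440 per-minute non-negative integer counts."""

    cat_id: str
    date: _dt.date
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_MINUTES_PER_DAY,):
            raise ValueError(
                f"EpochSeries needs exactly {N_MINUTES_PER_DAY} counts, "
                f"got shape {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def daytype(self) -> str:
        from .preprocessing import split_daytype

        return split_daytype(self.date)


@dataclass
class CatCovariates:
    """Subject-level covariates (one cat)."""

    cat_id: str
    group: str
    age: float
    bcs: int
    sex: str
    tpain: int
    tdjd: int
    study: str = ""
    max_single_joint_pain: int = 0

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CovariateError(f"{self.cat_id}: age must be > 0, got {self.age}")
        if not 1 <= self.bcs <= 9:
            raise CovariateError(f"{self.cat_id}: bcs must be 1-9, got {self.bcs}")
        if not 0 <= self.tpain <= 80:
            raise CovariateError(f"{self.cat_id}: tpain must be 0-80, got {self.tpain}")
        if not 0 <= self.tdjd <= 200:
            raise CovariateError(f"{self.cat_id}: tdjd must be 0-200, got {self.tdjd}")
        if not 0 <= self.max_single_joint_pain <= 4:
            raise CovariateError(
                f"{self.cat_id}: max_single_joint_pain must be 0-4, "
                f"got {self.max_single_joint_pain}"
            )


@dataclass
class EpochReadResult:
    """Complete subject-days plus a validation log of everything dropped."""

    series: list[EpochSeries]
    log: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)


def read_epoch_csv(path: str | Path) -> EpochReadResult:
    """Read the long-format per-minute CSV, returning only complete days.

    Days with fewer than 1440 distinct minutes are excluded and reported in
    the result's ``log``; duplicated minutes and negative or non-integer
    counts raise :class:`EpochParseError` with the offending file row number.
    """
    df = pd.read_csv(path, dtype={"cat_id": str, "date": str, "time": str})
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise EpochParseError(f"{path}: missing columns {missing}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is row 1
        raise EpochParseError(
            f"{path}: non-integer or negative count at file row {row}: "
            f"{df['count'].iloc[row - 2]!r}"
        )
    df = df.assign(count=counts.astype(np.int64))

    hhmm = df["time"].str.split(":", expand=True)
    try:
        minute = hhmm[0].astype(int) * 60 + hhmm[1].astype(int)
    except (ValueError, KeyError) as exc:
        raise EpochParseError(f"{path}: unparseable time label: {exc}") from exc
    df = df.assign(_minute=minute)

    series: list[EpochSeries] = []
    log: list[str] = []
    for (cat_id, date_str), day in df.groupby(["cat_id", "date"], sort=True):
        if day["_minute"].duplicated().any():
            dup = day.loc[day["_minute"].duplicated(), "time"].iloc[0]
            raise EpochParseError(
                f"{path}: duplicated minute {dup} for cat {cat_id} on {date_str}"
            )
        if len(day) != N_MINUTES_PER_DAY:
            log.append(
                f"dropped incomplete day: cat {cat_id} date {date_str} "
                f"({len(day)}/{N_MINUTES_PER_DAY} minutes)"
            )
            continue
        day = day.sort_values("_minute")
        series.append(
            EpochSeries(
                cat_id=str(cat_id),
                date=_dt.date.fromisoformat(date_str),
                counts=day["count"].to_numpy(),
            )
        )
    return EpochReadResult(series=series, log=log)


def write_epoch_csv(series: list[EpochSeries], path: str | Path) -> Path:
    """Write series to the long-format CSV, deterministically ordered.

    Rows are sorted by (cat_id, date, minute); dates are ISO-8601, times
    HH:MM, output UTF-8 with LF line endings.
    """
    path = Path(path)
    ordered = sorted(series, key=lambda s: (s.cat_id, s.date))
    times = [f"{m // 60:02d}:{m % 60:02d}" for m in range(N_MINUTES_PER_DAY)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(EPOCH_COLUMNS) + "\n")
        for s in ordered:
            date = s.date.isoformat()
            for t, c in zip(times, s.counts):
                fh.write(f"{s.cat_id},{date},{t},{c}\n")
    return path


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the covariate table; returns a DataFrame indexed 0..n-1."""
    df = pd.read_csv(path, dtype={"cat_id": str, "group": str, "study": str, "sex": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns and c != "study"]
    if missing:
        raise CovariateError(f"{path}: missing columns {missing}")
    if "study" not in df.columns:
        df["study"] = df["group"]
    # route every row through CatCovariates for range validation
    for row in df.itertuples(index=False):
        CatCovariates(
            cat_id=row.cat_id,
            group=row.group,
            study=row.study,
            age=float(row.age),
            bcs=int(row.bcs),
            sex=row.sex,
            tpain=int(row.tpain),
            tdjd=int(row.tdjd),
            max_single_joint_pain=int(row.max_single_joint_pain),
        )
    return df.reset_index(drop=True)


def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = covariates[COVARIATE_COLUMNS].sort_values("cat_id")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


#: total-pain-score category cut-offs (upper bounds, inclusive)
PAIN_CATEGORIES = [(2, "negligible"), (4, "low"), (9, "moderate")]
#: total-DJD-score category cut-offs (upper bounds, inclusive)
DJD_CATEGORIES = [(3, "negligible"), (12, "low"), (24, "moderate")]


def categorize_scores(
    tpain: int, tdjd: int, max_single_joint_pain: int = 0
) -> tuple[str, str]:
    """Map total pain and total DJD scores to their ordinal categories.

    Pain: 0-2 negligible — unless any single joint scored 2, which promotes
    the cat to the low category; 2-4 low; 5-9 moderate; >=10 high.
    DJD: 0-3 negligible; 4-12 low; 13-24 moderate; >=25 high.
    """
    if not 0 <= tpain <= 80:
        raise CovariateError(f"tpain out of range 0-80: {tpain}")
    if not 0 <= tdjd <= 200:
        raise CovariateError(f"tdjd out of range 0-200: {tdjd}")
    if not 0 <= max_single_joint_pain <= 4:
        raise CovariateError(
            f"max_single_joint_pain out of range 0-4: {max_single_joint_pain}"
        )

    if tpain <= 2 and max_single_joint_pain >= 2:
        pain = "low"
    else:
        pain = "high"
        for hi, label in PAIN_CATEGORIES:
            if tpain <= hi:
                pain = label
                break

    djd = "high"
    for hi, label in DJD_CATEGORIES:
        if tdjd <= hi:
            djd = label
            break
    return pain, djd
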