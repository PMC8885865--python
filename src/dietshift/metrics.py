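"""Surplus-of-interest metrics and year-over-year relative change.

The *surplus of interest* expresses a week's interest as a z-score
relative to the baseline-year (2019) mean and standard deviation of the
same series, which makes surges comparable across series on different
volume scales and lets them be benchmarked against known disruptions such
as the Christmas or Thanksgiving week.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import scipy.stats

from .series import BASELINE_YEAR, TREATMENT_YEAR, InterestSeries, week_of

logger = logging.getLogger(__name__)

#: Week of the 52-week grid containing December 25, 2019.
CHRISTMAS_WEEK_2019: tuple[int, int] = (BASELINE_YEAR, week_of(date(2019, 12, 25)))


def thanksgiving_week(year: int = BASELINE_YEAR) -> tuple[int, int]:
    """(year, week) of the US Thanksgiving week (fourth Thursday of November)."""
    d = date(year, 11, 1)
    # first Thursday of November, then three weeks on
    d += timedelta(days=(3 - d.weekday()) % 7)
    return (year, week_of(d + timedelta(weeks=3)))


@dataclass(frozen=True)
class ZScoreSeries:
    """An interest series standardized by its 2019 mean and SD."""

    base: InterestSeries
    mu_2019: float
    sigma_2019: float
    z: pd.DataFrame  # columns year, week, z

    def z_at(self, year: int, week: int) -> float:
        sub = self.z[(self.z["year"] == year) & (self.z["week"] == week)]
        if len(sub) == 0:
            raise ValueError(
                f"{self.base.label!r}: no z-value for year {year}, week {week}"
            )
        return float(sub["z"].iloc[0])


@dataclass(frozen=True)
class SurplusReport:
    """Peak and cumulative surplus relative to a reference holiday week."""

    ref_week: tuple[int, int]
    peak_ratio: float
    window_ratio: float
    window: tuple[int, int]  # weeks of 2020, inclusive
    peak_week: int

    def __post_init__(self) -> None:
        if self.window[1] < self.window[0]:
            raise ValueError("empty surplus window")
        if not (np.isfinite(self.peak_ratio) and np.isfinite(self.window_ratio)):
            raise ValueError("surplus ratios must be finite")


def zscore_series(s: InterestSeries) -> ZScoreSeries:
    """Standardize a series by its baseline-year mean and SD.

    ``z = (y - mu_2019) / sigma_2019`` for every week of both years, with
    ``mu``/``sigma`` computed over the 2019 weeks only (sample SD, ddof=1).
    By construction the 2019 z-values have mean 0 and SD 1; the transform
    is invariant to any positive affine rescaling of the volumes, so the
    result does not depend on the calibration scale.
    """
    y2019 = s.volumes(BASELINE_YEAR)
    if len(y2019) < 2:
        raise ValueError(f"{s.label!r}: need >= 2 baseline-year observations")
    mu = float(y2019.mean())
    sigma = float(y2019.std(ddof=1))
    if sigma <= 0:
        raise ValueError(f"{s.label!r}: zero variance in baseline year")
    z = s.data.copy()
    z["z"] = (z["volume"] - mu) / sigma
    return ZScoreSeries(s, mu, sigma, z[["year", "week", "z"]])


def surplus_ratio(
    z: ZScoreSeries, week: tuple[int, int], ref_week: tuple[int, int]
) -> float:
    """z-score of ``week`` relative to the z-score of a reference week.

    The reference z must be positive — a surplus comparison against a
    week that was itself at or below the baseline mean is undefined.
    """
    ref = z.z_at(*ref_week)
    if ref <= 0:
        raise ValueError(
            f"reference week {ref_week} has non-positive z ({ref:.3f})"
        )
    return z.z_at(*week) / ref


def cumulative_surplus_ratio(
    z: ZScoreSeries,
    window: tuple[int, int],
    ref_week: tuple[int, int],
) -> float:
    """Sum of 2020 z-values over ``window`` relative to the reference z.

    ``window`` is an inclusive (start_week, end_week) range of 2020.  The
    sum is signed: weeks below the baseline mean subtract.  The metric is
    additive over disjoint windows.
    """
    start, end = window
    if end < start:
        raise ValueError("empty surplus window")
    ref = z.z_at(*ref_week)
    if ref <= 0:
        raise ValueError(
            f"reference week {ref_week} has non-positive z ({ref:.3f})"
        )
    sub = z.z[
        (z.z["year"] == TREATMENT_YEAR)
        & (z.z["week"] >= start)
        & (z.z["week"] <= end)
    ]
    if len(sub) == 0:
        raise ValueError(f"no 2020 observations in window {window}")
    return float(sub["z"].sum()) / ref


def surplus_report(
    z: ZScoreSeries,
    window: tuple[int, int] = (1, 26),
    ref_week: tuple[int, int] = CHRISTMAS_WEEK_2019,
) -> SurplusReport:
    """Peak and cumulative surplus of the 2020 window vs a holiday week.

    The peak is the raw maximum weekly z-value within the window (no
    smoothing); the default window, weeks 1–26, is the first half of 2020
    on the weekly grid.
    """
    sub = z.z[
        (z.z["year"] == TREATMENT_YEAR)
        & (z.z["week"] >= window[0])
        & (z.z["week"] <= window[1])
    ]
    if len(sub) == 0:
        raise ValueError(f"no 2020 observations in window {window}")
    peak_row = sub.loc[sub["z"].idxmax()]
    peak_week = int(peak_row["week"])
    return SurplusReport(
        ref_week=ref_week,
        peak_ratio=surplus_ratio(z, (TREATMENT_YEAR, peak_week), ref_week),
        window_ratio=cumulative_surplus_ratio(z, window, ref_week),
        window=window,
        peak_week=peak_week,
    )


def relative_change(y2020, y2019):
    """Year-over-year relative change ``(y2020 - y2019) / y2019``."""
    y2019 = np.asarray(y2019, dtype=float)
    y2020 = np.asarray(y2020, dtype=float)
    if np.any(y2019 <= 0):
        raise ValueError("baseline-year volume must be > 0")
    out = (y2020 - y2019) / y2019
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RelativeChangeSummary:
    """Country-level average year-over-year change with a t-based 95% CI."""

    weekly: pd.Series  # indexed by week-of-year
    mean: float
    ci_low: float
    ci_high: float
    n: int
    excluded_weeks: tuple[int, ...]


def relative_change_summary(s: InterestSeries) -> RelativeChangeSummary:
    """Weekly relative change 2020 vs corresponding weeks of 2019.

    Weeks whose 2019 volume is zero are excluded (and logged) rather than
    producing infinities; the summary is the mean over the remaining
    weekly values with a Student-t 95% confidence interval.
    """
    y2019 = s.volumes(BASELINE_YEAR)
    y2020 = s.volumes(TREATMENT_YEAR)
    common = y2019.index.intersection(y2020.index)
    excluded = tuple(int(w) for w in common if y2019[w] <= 0)
    if excluded:
        logger.info(
            "%s (%s): excluding %d week(s) with zero 2019 volume: %s",
            s.label,
            s.country,
            len(excluded),
            excluded,
        )
    weeks = [w for w in common if w not in excluded]
    if len(weeks) < 2:
        raise ValueError(f"{s.label!r}: fewer than 2 usable weeks")
    weekly = pd.Series(
        [(y2020[w] - y2019[w]) / y2019[w] for w in weeks], index=weeks
    )
    n = len(weekly)
    mean = float(weekly.mean())
    sem = float(weekly.std(ddof=1)) / np.sqrt(n)
    half = float(scipy.stats.t.ppf(0.975, n - 1)) * sem
    return RelativeChangeSummary(
        weekly=weekly,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
        excluded_weeks=excluded,
    )
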