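"""Mobility smoothing, changepoint detection and lockdown severity.

Changes in population mobility are read off the residential component of
the Google COVID-19 Community Mobility Reports: the percentage by which
time spent in residential areas differs from a pre-pandemic baseline.
Rather than relying on official lockdown decree dates — which map onto
actual behaviour inconsistently across countries — the onset and end of
reduced mobility are detected directly from the data: the smoothed series
crossing a +10% threshold marks the start of a decreased-mobility period
(first or second wave), and the peak of the smoothed series within that
period is the lockdown *severity*.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import MobilitySeries, week_of

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 10.0
#: sub-threshold dips shorter than this many days do not end a period
MIN_DIP_DAYS = 3


@dataclass(frozen=True)
class ChangepointSet:
    """The three mobility changepoints and the peak severity.

    ``first_decrease`` — first date the smoothed series reaches the
    threshold (onset of reduced mobility); ``mobility_increase`` — first
    subsequent date it durably drops below; ``second_decrease`` — onset of
    the second wave, if any.  Absent fields mean the series never crossed.
    """

    first_decrease: pd.Timestamp | None
    mobility_increase: pd.Timestamp | None
    second_decrease: pd.Timestamp | None
    peak_severity: float | None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        dates = [
            d
            for d in (self.first_decrease, self.mobility_increase, self.second_decrease)
            if d is not None
        ]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("changepoints must be strictly ordered in time")
        if self.first_decrease is not None:
            if self.peak_severity is None or self.peak_severity < self.threshold:
                raise ValueError("peak severity below threshold despite a crossing")

    @property
    def cutoff_week(self) -> int | None:
        """Week-of-year of the onset (the RDD cutoff week, t = 0)."""
        return None if self.first_decrease is None else week_of(self.first_decrease)

    @property
    def second_cutoff_week(self) -> int | None:
        return None if self.second_decrease is None else week_of(self.second_decrease)


def smooth_weekly(m: MobilitySeries) -> MobilitySeries:
    """Centered 7-day rolling mean of the daily series.

    Date gaps are respected (the window is 7 calendar days, missing days
    simply contribute nothing); edge days use whatever part of the window
    exists, requiring at least 4 days.
    """
    if len(m) < 7:
        raise ValueError(
            f"{m.country}: need >= 7 daily observations to smooth, got {len(m)}"
        )
    full = m.values.reindex(
        pd.date_range(m.values.index[0], m.values.index[-1], freq="D")
    )
    sm = full.rolling(7, center=True, min_periods=4).mean()
    sm = sm[m.values.index].dropna()
    return MobilitySeries(m.country, sm)


def detect_changepoints(
    m: MobilitySeries, threshold: float = DEFAULT_THRESHOLD
) -> ChangepointSet:
    """Detect the onset, relaxation and second-wave onset by thresholding.

    The raw daily series is smoothed internally.  A decreased-mobility
    period starts on the first day the smoothed series reaches the
    threshold; it ends at the first *sustained* drop below (brief dips
    shorter than ``MIN_DIP_DAYS`` days are ignored and logged).  The
    second-wave onset is the first crossing after the period ends.
    """
    if len(m) == 0:
        raise ValueError("empty mobility series")
    sm = smooth_weekly(m)
    v = sm.values.to_numpy()
    dates = sm.values.index
    above = v >= threshold

    idx_first = _first_true(above, 0)
    if idx_first is None:
        return ChangepointSet(None, None, None, None, threshold)

    idx_increase = _first_sustained_drop(above, idx_first, dates, m.country)
    if idx_increase is None:
        peak = float(v[idx_first:].max())
        return ChangepointSet(dates[idx_first], None, None, peak, threshold)

    peak = float(v[idx_first:idx_increase].max())
    idx_second = _first_true(above, idx_increase)
    second = None if idx_second is None else dates[idx_second]
    return ChangepointSet(dates[idx_first], dates[idx_increase], second, peak, threshold)


def _first_true(mask: np.ndarray, start: int) -> int | None:
    hits = np.nonzero(mask[start:])[0]
    return None if len(hits) == 0 else start + int(hits[0])


def _first_sustained_drop(
    above: np.ndarray, start: int, dates, country: str
) -> int | None:
    """First index after ``start`` opening a below-threshold run of
    >= MIN_DIP_DAYS days (or one running to the end of the series)."""
    i = start
    n = len(above)
    while i < n:
        nxt = _first_true(~above, i)
        if nxt is None:
            return None
        run_end = nxt
        while run_end < n and not above[run_end]:
            run_end += 1
        if run_end - nxt >= MIN_DIP_DAYS or run_end == n:
            return nxt
        logger.info(
            "%s: ignoring %d-day sub-threshold dip at %s",
            country,
            run_end - nxt,
            dates[nxt].date(),
        )
        i = run_end
    return None


def peak_severity(m: MobilitySeries, cp: ChangepointSet) -> float:
    """Peak of the smoothed series within the decreased-mobility period.

    The period runs from ``first_decrease`` to ``mobility_increase`` (or
    the end of the series if mobility never recovered).
    """
    if cp.first_decrease is None:
        raise ValueError("no decreased-mobility period detected")
    sm = smooth_weekly(m).values
    end = cp.mobility_increase
    window = sm[cp.first_decrease :] if end is None else sm[cp.first_decrease : end]
    if end is not None and len(window) and window.index[-1] == end:
        window = window.iloc[:-1]
    return float(window.max())


def read_mobility_reports(
    path: str | Path, countries: list[str] | None = None
) -> dict[str, MobilitySeries]:
    """Read a Community-Mobility-Reports-style CSV into per-country series.

    Uses the columns ``country_region_code``, ``date`` and
    ``residential_percent_change_from_baseline``; rows with a non-empty
    sub-region (or metro area) column are dropped so only country-level
    data remains.
    """
    df = pd.read_csv(path, dtype={"country_region_code": str})
    required = {"country_region_code", "date", "residential_percent_change_from_baseline"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mobility file {path}: missing columns {sorted(missing)}")
    for col in ("sub_region_1", "sub_region_2", "metro_area"):
        if col in df.columns:
            df = df[df[col].isna() | (df[col].astype(str).str.strip() == "")]
    if countries is not None:
        df = df[df["country_region_code"].isin(countries)]
    out: dict[str, MobilitySeries] = {}
    for code, sub in df.groupby("country_region_code"):
        s = pd.Series(
            sub["residential_percent_change_from_baseline"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(pd.to_datetime(sub["date"])),
        ).sort_index()
        out[str(code)] = MobilitySeries(str(code), s)
    logger.info("read mobility series for %d countries from %s", len(out), path)
    return out


def write_mobility_reports(
    series: dict[str, MobilitySeries] | list[MobilitySeries], path: str | Path
) -> None:
    """Write per-country series in the mobility-reports CSV dialect."""
    if isinstance(series, dict):
        series = list(series.values())
    frames = []
    for m in series:
        frames.append(
            pd.DataFrame(
                {
                    "country_region_code": m.country,
                    "sub_region_1": "",
                    "sub_region_2": "",
                    "date": m.values.index.strftime("%Y-%m-%d"),
                    "residential_percent_change_from_baseline": m.values.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
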