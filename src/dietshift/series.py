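"""Core time-series containers shared across the analysis.

Two kinds of series flow through the pipeline:

* :class:`InterestSeries` — calibrated weekly search-interest volume for one
  entity (or aggregated group of entities) in one country, on a 52-week grid
  covering a baseline year (2019) and a treatment year (2020).  Calibration
  means the volumes of different entities share one multiplicative scale, so
  series can be summed and compared.
* :class:`MobilitySeries` — daily residential-mobility percent change from a
  pre-pandemic baseline for one country (the layout of the Google COVID-19
  Community Mobility Reports).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEEKS_PER_YEAR = 52
BASELINE_YEAR = 2019
TREATMENT_YEAR = 2020


def week_of(date) -> int:
    """Week-of-year of ``date`` on the 52-week grid.

    ISO week 53 (a handful of days at the turn of the year) folds into
    week 52, so every date maps into ``[1, 52]``.
    """
    return int(min(pd.Timestamp(date).isocalendar().week, WEEKS_PER_YEAR))


@dataclass(frozen=True)
class InterestSeries:
    """Weekly calibrated search-interest volumes for one entity/group.

    Parameters
    ----------
    country
        ISO country code.
    label
        Entity identifier or group name.
    data
        DataFrame with columns ``year``, ``week`` (1–52) and ``volume``
        (non-negative, calibrated search-volume units).  At most one
        observation per (year, week); rows are sorted on construction.
    """

    country: str
    label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = {"year", "week", "volume"} - set(df.columns)
        if missing:
            raise ValueError(f"interest series missing columns {sorted(missing)}")
        df = df[["year", "week", "volume"]]
        df["year"] = df["year"].astype(int)
        df["week"] = df["week"].astype(int)
        df["volume"] = df["volume"].astype(float)
        if len(df) == 0:
            raise ValueError(f"empty interest series {self.label!r}")
        if df["week"].min() < 1 or df["week"].max() > WEEKS_PER_YEAR:
            raise ValueError(
                f"{self.label!r}: weeks must lie in [1, {WEEKS_PER_YEAR}]"
            )
        if not np.isfinite(df["volume"]).all() or (df["volume"] < 0).any():
            raise ValueError(f"{self.label!r}: volumes must be finite and >= 0")
        if df.duplicated(["year", "week"]).any():
            raise ValueError(f"{self.label!r}: duplicate (year, week) observation")
        df = df.sort_values(["year", "week"], ignore_index=True)
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["year"].unique()))

    def volumes(self, year: int) -> pd.Series:
        """Volumes of one year, indexed by week-of-year."""
        sub = self.data[self.data["year"] == year]
        return pd.Series(sub["volume"].to_numpy(), index=sub["week"].to_numpy())

    def volume_at(self, year: int, week: int) -> float:
        sub = self.data[(self.data["year"] == year) & (self.data["week"] == week)]
        if len(sub) == 0:
            raise ValueError(
                f"{self.label!r} ({self.country}): no observation for "
                f"year {year}, week {week}"
            )
        return float(sub["volume"].iloc[0])

    def with_volumes(self, volumes: np.ndarray, label: str | None = None) -> "InterestSeries":
        """Same grid, new volumes (and optionally a new label)."""
        df = self.data.copy()
        df["volume"] = np.asarray(volumes, dtype=float)
        return InterestSeries(self.country, label if label is not None else self.label, df)

    def same_grid(self, other: "InterestSeries") -> bool:
        a = self.data[["year", "week"]].to_numpy()
        b = other.data[["year", "week"]].to_numpy()
        return a.shape == b.shape and bool((a == b).all())


@dataclass(frozen=True)
class MobilitySeries:
    """Daily residential percent-change from a pre-pandemic baseline.

    ``values`` is a float Series indexed by strictly increasing dates, on
    the percent scale (e.g. ``+25.0`` means 25% more time at home than
    baseline).  Gaps between dates are allowed but logged.
    """

    country: str
    values: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.values).copy()
        s.index = pd.DatetimeIndex(s.index)
        s = s.astype(float)
        if len(s) == 0:
            raise ValueError(f"empty mobility series for {self.country!r}")
        if s.index.has_duplicates:
            raise ValueError(f"{self.country!r}: duplicate mobility dates")
        if not s.index.is_monotonic_increasing:
            raise ValueError(f"{self.country!r}: mobility dates must increase")
        gaps = np.diff(s.index.to_numpy()) > np.timedelta64(1, "D")
        if gaps.any():
            logger.info(
                "mobility series %s has %d date gap(s)", self.country, int(gaps.sum())
            )
        object.__setattr__(self, "values", s)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start(self) -> pd.Timestamp:
        return self.values.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.values.index[-1]
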