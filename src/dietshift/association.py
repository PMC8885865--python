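"""Mobility–interest correlations and the dose-response analysis.

Two cross-sectional questions complement the regression-discontinuity
effect estimates: within a country, do weeks with more time spent at home
show larger year-over-year shifts in interest (Spearman rank correlation,
which is seasonality-adjusted because the interest signal is the relative
change against the corresponding week of 2019)?  And across countries, do
harsher lockdowns produce larger short-term effects (the dose-response
Pearson correlation and least-squares line)?
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .series import BASELINE_YEAR, TREATMENT_YEAR, InterestSeries, MobilitySeries, week_of
from .rdd import EffectEstimate

logger = logging.getLogger(__name__)

#: first full week of February through the end of December 2020 — 46 weeks
DEFAULT_WINDOW = (6, 51)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if self.n < 4:
            raise ValueError("need at least 4 weeks")


@dataclass(frozen=True)
class DoseResponseResult:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    excluded: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def weekly_mobility(m: MobilitySeries, year: int = TREATMENT_YEAR) -> pd.Series:
    """Mean of the available daily values per week-of-year.

    Weeks are the same 52-week grid as the interest series (week 53 days
    fold into week 52); weeks without any daily observation are simply
    absent from the result.
    """
    sub = m.values[m.values.index.year == year]
    if len(sub) == 0:
        raise ValueError(f"{m.country}: no mobility observations in {year}")
    weeks = np.array([week_of(d) for d in sub.index])
    return sub.groupby(weeks).mean()


def mobility_interest_correlation(
    interest: InterestSeries,
    m: MobilitySeries,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> SpearmanResult:
    """Spearman correlation of weekly mobility with relative interest change.

    For each 2020 week in ``window`` (inclusive; the default spans the
    first full week of February through the end of December, 46 weeks),
    interest is expressed as the relative change against the
    corresponding week of 2019, and correlated with the weekly mean
    residential mobility.  Ties are handled by average ranks; the p-value
    is the two-sided t-test ``t = rho * sqrt((n - 2) / (1 - rho**2))``
    under the null of no correlation.
    """
    wk_mob = weekly_mobility(m)
    y2019 = interest.volumes(BASELINE_YEAR)
    y2020 = interest.volumes(TREATMENT_YEAR)
    xs, ys = [], []
    for w in range(window[0], window[1] + 1):
        if w not in wk_mob.index or w not in y2019.index or w not in y2020.index:
            continue
        if y2019[w] <= 0:
            logger.info(
                "%s (%s): skipping week %d with zero 2019 volume",
                interest.label, interest.country, w,
            )
            continue
        xs.append(wk_mob[w])
        ys.append((y2020[w] - y2019[w]) / y2019[w])
    n = len(xs)
    if n < 4:
        raise ValueError(f"only {n} usable weeks in window {window}; need >= 4")
    rho, p = scipy.stats.spearmanr(xs, ys)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=n)


def dose_response(
    severity: dict[str, float],
    effects: dict[str, EffectEstimate],
    exclude: list[str] | tuple[str, ...] = (),
    scale: str = "log",
) -> DoseResponseResult:
    """Cross-country correlation of lockdown severity with the effect size.

    ``severity`` maps country code to the peak residential-mobility
    increase (percent); ``effects`` to the estimated short-term effect.
    On the default ``scale="log"`` the response variable is the log-scale
    coefficient ``alpha``, on which a linear severity coupling is linear;
    ``scale="linear"`` uses ``e**alpha - 1`` instead.  Countries listed in
    ``exclude`` are dropped and recorded; excluding an absent country is
    a no-op.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    common = sorted(set(severity) & set(effects))
    excluded = tuple(c for c in exclude if c in common)
    used = [c for c in common if c not in excluded]
    if len(used) < 3:
        raise ValueError(f"only {len(used)} countries after exclusion; need >= 3")
    x = np.array([severity[c] for c in used], dtype=float)
    y = np.array(
        [
            effects[c].log_effect if scale == "log" else effects[c].point
            for c in used
        ],
        dtype=float,
    )
    r, p = scipy.stats.pearsonr(x, y)
    lin = scipy.stats.linregress(x, y)
    if excluded:
        logger.info("dose-response excluded countries: %s", list(excluded))
    return DoseResponseResult(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        excluded=excluded,
        n=len(used),
    )
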