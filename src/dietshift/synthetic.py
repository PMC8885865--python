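"""Synthetic interest and mobility panels with known ground truth.

The generators emulate the data the pipeline is built for: two years of
weekly multiplicative search-interest series sharing a seasonal component
(with end-of-year holiday peaks), to which the treatment year adds a
post-cutoff multiplicative shock with polynomial decay; and daily
residential-mobility series with a sigmoid lockdown onset, plateau,
recovery and optional second wave.

Because the injected shock is exactly the interaction block of the
difference-in-discontinuities regression (see :mod:`dietshift.rdd`), a
noiseless generated series is *nested* in the fitted model and the shock
coefficients are exactly recoverable — which is what makes every
downstream stage testable without external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .series import (
    BASELINE_YEAR,
    TREATMENT_YEAR,
    WEEKS_PER_YEAR,
    InterestSeries,
    MobilitySeries,
    week_of,
)

__all__ = [
    "SeasonalShockParams",
    "MobilityShockParams",
    "CountryTruth",
    "SyntheticPanel",
    "generate_interest_series",
    "generate_mobility_series",
    "generate_country_panel",
    "GROUP_EFFECT_MULTIPLIERS",
    "CATEGORY_EFFECT_MULTIPLIERS",
]


@dataclass(frozen=True)
class SeasonalShockParams:
    """Generative parameters of one weekly interest series.

    The log volume of week-of-year ``w`` in year ``T`` is

    ``log(baseline_level) + trend_per_week * t + holiday bump
    + 1[T = 2020, t > 0] * (alpha + beta * t + gamma * t**2) + eps``

    with ``t = w - cutoff_week_of_year``,
    ``(alpha, beta, gamma) = (shock_log_effect, *shock_decay)``, a bump of
    ``log(holiday_multiplier)`` in holiday weeks of *both* years, and
    ``eps ~ Normal(0, noise_sigma**2)`` (i.e. lognormal multiplicative
    noise, matching the log-OLS error model of the fit).
    """

    baseline_level: float = 100.0
    trend_per_week: float = 0.0
    holiday_weeks: tuple[int, ...] = (51, 52)
    holiday_multiplier: float = 1.5
    shock_log_effect: float = math.log(1.5)
    shock_decay: tuple[float, float] = (-0.01, 0.0002)
    cutoff_week_of_year: int = 12
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_level > 0:
            raise ValueError("baseline_level must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.holiday_multiplier < 1:
            raise ValueError("holiday_multiplier must be >= 1")
        if not 1 <= self.cutoff_week_of_year <= WEEKS_PER_YEAR:
            raise ValueError("cutoff_week_of_year must lie in [1, 52]")
        for w in self.holiday_weeks:
            if not 1 <= w <= WEEKS_PER_YEAR:
                raise ValueError("holiday weeks must lie in [1, 52]")


@dataclass(frozen=True)
class MobilityShockParams:
    """Generative parameters of one daily residential-mobility series.

    The noiseless profile is 0 before ``onset_day``, rises smoothly
    (smoothstep) over ``rise_days`` to exactly ``peak_severity``, holds for
    ``plateau_days``, decays back to 0 over ``recovery_days``, and — when a
    second wave is configured — rises again at ``second_onset_day`` to
    ``second_peak_severity`` and holds through the end of the series.
    Gaussian noise with SD ``noise_sigma`` (percent) is added on top.
    """

    onset_day: date = date(2020, 3, 15)
    peak_severity: float = 25.0
    rise_days: int = 14
    plateau_days: int = 30
    recovery_days: int = 90
    second_onset_day: date | None = None
    second_peak_severity: float | None = None
    noise_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_severity < 0:
            raise ValueError("peak_severity must be >= 0")
        if self.rise_days <= 0 or self.recovery_days <= 0 or self.plateau_days < 0:
            raise ValueError("rise/recovery days must be > 0, plateau >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if (self.second_onset_day is None) != (self.second_peak_severity is None):
            raise ValueError("second wave needs both onset day and peak severity")
        if self.second_onset_day is not None:
            first_wave_end = (
                pd.Timestamp(self.onset_day)
                + pd.Timedelta(days=self.rise_days + self.plateau_days + self.recovery_days)
            )
            if pd.Timestamp(self.second_onset_day) < first_wave_end:
                raise ValueError(
                    "second wave onset overlaps the first wave "
                    f"(first wave ends {first_wave_end.date()})"
                )
            if self.second_peak_severity is not None and self.second_peak_severity < 0:
                raise ValueError("second_peak_severity must be >= 0")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Monotone sigmoid ramp on [0, 1] with s(0)=0, s(1)=1."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_interest_series(
    params: SeasonalShockParams,
    country: str = "XX",
    label: str = "synthetic",
) -> InterestSeries:
    """Generate a two-year weekly interest series (104 observations).

    Both years carry the same seasonal component (trend + holiday bumps);
    only the treatment year (2020) receives the post-cutoff shock.  The
    same seed always yields the same series.
    """
    rng = np.random.default_rng(params.seed)
    alpha = params.shock_log_effect
    beta, gamma = params.shock_decay
    holiday = set(params.holiday_weeks)

    rows = []
    for year in (BASELINE_YEAR, TREATMENT_YEAR):
        for week in range(1, WEEKS_PER_YEAR + 1):
            t = week - params.cutoff_week_of_year
            log_y = math.log(params.baseline_level) + params.trend_per_week * t
            if week in holiday:
                log_y += math.log(params.holiday_multiplier)
            if year == TREATMENT_YEAR and t > 0:
                log_y += alpha + beta * t + gamma * t * t
            rows.append((year, week, log_y))
    log_y = np.array([r[2] for r in rows])
    if params.noise_sigma > 0:
        log_y = log_y + rng.normal(0.0, params.noise_sigma, size=len(rows))
    df = pd.DataFrame(
        {
            "year": [r[0] for r in rows],
            "week": [r[1] for r in rows],
            "volume": np.exp(log_y),
        }
    )
    return InterestSeries(country, label, df)


def mobility_profile(params: MobilityShockParams, dates: pd.DatetimeIndex) -> np.ndarray:
    """Noiseless mobility profile of ``params`` evaluated at ``dates``."""
    rel = (dates - pd.Timestamp(params.onset_day)).days.to_numpy().astype(float)
    v = np.zeros(len(dates))

    rise_end = params.rise_days
    plateau_end = rise_end + params.plateau_days
    recovery_end = plateau_end + params.recovery_days

    rising = (rel > 0) & (rel <= rise_end)
    v[rising] = params.peak_severity * _smoothstep(rel[rising] / params.rise_days)
    v[(rel > rise_end) & (rel <= plateau_end)] = params.peak_severity
    recovering = (rel > plateau_end) & (rel <= recovery_end)
    v[recovering] = params.peak_severity * (
        1.0 - _smoothstep((rel[recovering] - plateau_end) / params.recovery_days)
    )

    if params.second_onset_day is not None:
        rel2 = (dates - pd.Timestamp(params.second_onset_day)).days.to_numpy().astype(float)
        rising2 = (rel2 > 0) & (rel2 <= params.rise_days)
        v[rising2] = params.second_peak_severity * _smoothstep(rel2[rising2] / params.rise_days)
        v[rel2 > params.rise_days] = params.second_peak_severity
    return v


def generate_mobility_series(
    params: MobilityShockParams, country: str = "XX"
) -> MobilitySeries:
    """Generate a daily mobility series spanning February–December.

    The simulated year is taken from ``params.onset_day``.  With
    ``noise_sigma = 0`` the maximum of the series equals ``peak_severity``
    exactly and all pre-onset days are exactly 0.
    """
    year = params.onset_day.year
    dates = pd.date_range(date(year, 2, 1), date(year, 12, 31), freq="D")
    v = mobility_profile(params, dates)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.noise_sigma, size=len(dates))
    return MobilitySeries(country, pd.Series(v, index=dates))


# Access-mode groups: {consumed at home / outside} x {prepared by household /
# third party}.  Multipliers set the sign and size of each group's shock
# relative to the country-level base effect: staying home boosts home
# cooking and delivery, depresses eating out.
GROUP_EFFECT_MULTIPLIERS: dict[str, float] = {
    "household_home": 1.0,
    "third_party_home": 1.0,
    "household_outside": -0.5,
    "third_party_outside": -1.0,
}

# A small food-category slate for end-to-end runs; multipliers relative to
# the base effect (comfort/baking categories surge more than staples).
CATEGORY_EFFECT_MULTIPLIERS: dict[str, float] = {
    "pastries_bakery": 1.0,
    "desserts": 0.8,
    "vegetables": 0.3,
}


@dataclass(frozen=True)
class CountryTruth:
    """Ground truth recorded for one simulated country."""

    severity: float
    alpha: dict[str, float]  # per series label, log scale


@dataclass(frozen=True)
class SyntheticPanel:
    """A multi-country panel of interest and mobility series with truth."""

    countries: tuple[str, ...]
    interest: dict[str, dict[str, InterestSeries]]  # country -> label -> series
    mobility: dict[str, MobilitySeries]
    truth: dict[str, CountryTruth]
    dose_slope: float

    def __post_init__(self) -> None:
        for c in self.countries:
            if c not in self.interest or c not in self.mobility:
                raise ValueError(f"country {c!r} missing interest or mobility record")


def generate_country_panel(
    n_countries: int,
    severity_range: tuple[float, float] = (10.1, 31.6),
    dose_slope: float = 2.0,
    seed: int = 0,
    noise_sigma: float = 0.1,
    mobility_noise_sigma: float = 1.5,
    country_noise_sigma: float = 0.0,
    onset_day: date = date(2020, 3, 15),
    second_wave: bool = False,
) -> SyntheticPanel:
    """Generate a panel of countries with a known severity→effect coupling.

    Lockdown severities are spread evenly over ``severity_range`` and each
    country's base shock is ``alpha = dose_slope * severity / 100`` (plus
    optional Gaussian country noise), so the cross-country dose-response is
    linear on the log scale by construction.  Each country receives one
    interest series per access-mode group and per food category (multiplied
    by the group multipliers above), plus a ``total_food`` aggregate.

    The interest cutoff of each country is the week its *noiseless*
    mobility profile first reaches the +10% threshold — the same event the
    changepoint detector looks for — so the recorded truth matches what
    the end-to-end pipeline estimates.
    """
    if n_countries < 3:
        raise ValueError("need at least 3 countries")
    lo, hi = severity_range
    if hi <= lo and n_countries > 1:
        raise ValueError("severity_range must have positive width")
    severities = np.linspace(lo, hi, n_countries)
    rng = np.random.default_rng(seed)

    countries = tuple(f"C{i:02d}" for i in range(n_countries))
    interest: dict[str, dict[str, InterestSeries]] = {}
    mobility: dict[str, MobilitySeries] = {}
    truth: dict[str, CountryTruth] = {}

    labels = {**GROUP_EFFECT_MULTIPLIERS, **CATEGORY_EFFECT_MULTIPLIERS}
    for country, severity in zip(countries, severities):
        base_alpha = dose_slope * severity / 100.0
        if country_noise_sigma > 0:
            base_alpha += rng.normal(0.0, country_noise_sigma)
        second = (
            dict(
                second_onset_day=date(onset_day.year, 10, 15),
                second_peak_severity=0.6 * severity,
            )
            if second_wave
            else {}
        )
        mob_params = MobilityShockParams(
            onset_day=onset_day,
            peak_severity=float(severity),
            noise_sigma=mobility_noise_sigma,
            seed=int(rng.integers(2**31)),
            **second,
        )
        mobility[country] = generate_mobility_series(mob_params, country=country)
        cutoff_week = true_threshold_crossing_week(mob_params, threshold=10.0)
        alphas: dict[str, float] = {}
        series: dict[str, InterestSeries] = {}
        for label, mult in labels.items():
            alpha = mult * base_alpha
            series[label] = generate_interest_series(
                SeasonalShockParams(
                    shock_log_effect=alpha,
                    shock_decay=(-alpha / 60.0, 0.0),
                    cutoff_week_of_year=cutoff_week,
                    noise_sigma=noise_sigma,
                    seed=int(rng.integers(2**31)),
                ),
                country=country,
                label=label,
            )
            alphas[label] = alpha
        food = [series[c] for c in CATEGORY_EFFECT_MULTIPLIERS]
        total = food[0].data["volume"].to_numpy().copy()
        for s in food[1:]:
            total = total + s.data["volume"].to_numpy()
        series["total_food"] = food[0].with_volumes(total, label="total_food")
        alphas["total_food"] = float("nan")  # aggregate of shocked series
        interest[country] = series
        truth[country] = CountryTruth(severity=float(severity), alpha=alphas)

    return SyntheticPanel(countries, interest, mobility, truth, dose_slope)


def true_threshold_crossing_day(
    params: MobilityShockParams, threshold: float = 10.0
) -> pd.Timestamp:
    """First day the noiseless mobility profile reaches ``threshold``.

    Brute-force scan of the exact generative profile; this is the ground
    truth the changepoint detector is meant to recover.
    """
    year = params.onset_day.year
    dates = pd.date_range(date(year, 2, 1), date(year, 12, 31), freq="D")
    v = mobility_profile(params, dates)
    hits = np.nonzero(v >= threshold)[0]
    if len(hits) == 0:
        raise ValueError(f"profile never reaches threshold {threshold}")
    return dates[hits[0]]


def true_threshold_crossing_week(
    params: MobilityShockParams, threshold: float = 10.0
) -> int:
    """Week-of-year of the true threshold crossing (the RDD cutoff)."""
    return week_of(true_threshold_crossing_day(params, threshold))
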