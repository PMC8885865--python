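"""Difference-in-discontinuities regression and its derived quantities.

The effect of the mobility-decrease shock on a weekly interest series is
estimated with a regression discontinuity design in time, run on the
treatment year (2020) *and* on the same weeks of the control year (2019),
where a "fake" discontinuity at the same cutoff absorbs seasonal
patterns.  In quadratic form::

    log y_tT = a' + b'.t + c'.t^2
             + a''.i  + b''.i.t  + c''.i.t^2
             + a'''.j + b'''.j.t + c'''.j.t^2
             + alpha.i.j + beta.i.j.t + gamma.i.j.t^2

with t the week relative to the cutoff (t in [-t_min, t_max]), i = 1 for
t > 0, and j = 1 in 2020.  Log outcomes make the model multiplicative.
The interaction block (alpha, beta, gamma) is the effect of the
discontinuity net of the control-year seasonal pattern; three derived
quantities summarize it:

* **short-term effect** — ``e**alpha - 1``, the multiplicative jump at
  the cutoff;
* **reversion time** — weeks until the fitted 2020 curve is no longer
  significantly different from the 2019-based counterfactual
  (overlapping 95% CIs);
* **long-term effect** — how elevated the fitted 2020 outcome remains at
  ``t_max`` relative to the same week of 2019.

Constant and linear model variants drop the higher-order time terms.
The model is fitted by OLS with classical standard errors; 95% intervals
are taken as +/- 2 standard errors throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .series import BASELINE_YEAR, TREATMENT_YEAR, WEEKS_PER_YEAR, InterestSeries

logger = logging.getLogger(__name__)

FORMS = ("constant", "linear", "quadratic")
#: design-matrix columns per model form, in blocks: base, i, j, interaction
_FORM_COLUMNS = {
    "constant": ("const", "i", "j", "ij"),
    "linear": ("const", "t", "i", "i_t", "j", "j_t", "ij", "ij_t"),
    "quadratic": (
        "const", "t", "t2",
        "i", "i_t", "i_t2",
        "j", "j_t", "j_t2",
        "ij", "ij_t", "ij_t2",
    ),
}
#: half-width of 95% intervals in standard errors
CI_SE_MULTIPLIER = 2.0


@dataclass(frozen=True)
class ModelSpec:
    """Bandwidth, cutoff and outcome of one regression fit.

    ``t_min`` weeks before and ``t_max`` weeks after the cutoff enter the
    fit (defaults 10 and 30: the cutoff falls at most 10 weeks into the
    year, and 30 post weeks stay clear of any second-wave shock, giving
    the canonical 82-row design).  ``cutoff`` is the week-of-year of the
    detected mobility decrease in 2020; the cutoff week itself is t = 0
    and is untreated (i = 1 only for t > 0).
    """

    form: str = "quadratic"
    t_min: int = 10
    t_max: int = 30
    cutoff: int = 12
    outcome: str = "log_volume"  # or "log_share"

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.t_min < 1 or self.t_max < 1:
            raise ValueError("t_min and t_max must be >= 1")
        if self.outcome not in ("log_volume", "log_share"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not 1 <= self.cutoff <= WEEKS_PER_YEAR:
            raise ValueError("cutoff must be a week-of-year in [1, 52]")
        if self.form == "quadratic" and (self.t_min < 3 or self.t_max < 3):
            raise ValueError("quadratic form needs >= 3 distinct t on each side")

    @property
    def columns(self) -> tuple[str, ...]:
        return _FORM_COLUMNS[self.form]


@dataclass(frozen=True)
class RDDFit:
    """OLS fit of the difference-in-discontinuities model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    n_obs: int
    df_resid: int
    residual_variance: float

    def __post_init__(self) -> None:
        c = self.cov.to_numpy()
        if not np.allclose(c, c.T):
            raise ValueError("coefficient covariance must be symmetric")

    @property
    def alpha(self) -> float:
        """Short-term log effect (the i.j interaction intercept)."""
        return float(self.params["ij"])

    @property
    def alpha_se(self) -> float:
        return float(self.bse["ij"])

    def feature_row(self, t: int, year: int) -> pd.Series:
        """Design-matrix row for week ``t`` of ``year``."""
        i = 1.0 if t > 0 else 0.0
        j = 1.0 if year == TREATMENT_YEAR else 0.0
        full = {
            "const": 1.0, "t": t, "t2": t * t,
            "i": i, "i_t": i * t, "i_t2": i * t * t,
            "j": j, "j_t": j * t, "j_t2": j * t * t,
            "ij": i * j, "ij_t": i * j * t, "ij_t2": i * j * t * t,
        }
        return pd.Series({c: full[c] for c in self.spec.columns}, dtype=float)

    def predict_log(self, t: int, year: int) -> tuple[float, float]:
        """Fitted mean log outcome at (t, year) and its standard error."""
        x = self.feature_row(t, year).to_numpy()
        fit = float(x @ self.params.to_numpy())
        se = float(np.sqrt(x @ self.cov.to_numpy() @ x))
        return fit, se


@dataclass(frozen=True)
class EffectEstimate:
    """A multiplicative effect ``e**a - 1`` with its 95% CI on that scale."""

    point: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    log_effect: float
    log_se: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("effect CI must contain the point estimate")


@dataclass(frozen=True)
class GapEstimate:
    """Fitted 2020 outcome vs the 2019-based counterfactual at week t."""

    t: int
    gap_2020: float
    gap_2019: float
    ci_2020: tuple[float, float]
    ci_2019: tuple[float, float]
    overlapping: bool

    def __post_init__(self) -> None:
        if not (self.ci_2020[0] <= self.gap_2020 <= self.ci_2020[1]):
            raise ValueError("2020 interval must contain its point estimate")
        if not (self.ci_2019[0] <= self.gap_2019 <= self.ci_2019[1]):
            raise ValueError("2019 interval must contain its point estimate")


@dataclass(frozen=True)
class ReversionResult:
    """Outcome of the reversion-time measurement."""

    status: str  # "reverted" | "never_differed" | "not_reverted"
    weeks: int | None = None

    def __post_init__(self) -> None:
        if self.status not in ("reverted", "never_differed", "not_reverted"):
            raise ValueError(f"unknown reversion status {self.status!r}")
        if (self.status == "reverted") != (self.weeks is not None):
            raise ValueError("weeks must be set exactly when status is 'reverted'")


def build_design(s: InterestSeries, spec: ModelSpec) -> pd.DataFrame:
    """One design row per (year, t) over the bandwidth window.

    Requires complete, strictly positive volumes over weeks
    ``[cutoff - t_min, cutoff + t_max]`` in both years; the default
    bandwidths give (10 + 30 + 1) x 2 = 82 rows.
    """
    if spec.cutoff - spec.t_min < 1 or spec.cutoff + spec.t_max > WEEKS_PER_YEAR:
        raise ValueError(
            f"window [cutoff-{spec.t_min}, cutoff+{spec.t_max}] around week "
            f"{spec.cutoff} leaves the 52-week grid"
        )
    rows = []
    for year in (BASELINE_YEAR, TREATMENT_YEAR):
        for t in range(-spec.t_min, spec.t_max + 1):
            week = spec.cutoff + t
            y = s.volume_at(year, week)  # missing week -> hard error
            if y <= 0:
                raise ValueError(
                    f"{s.label!r} ({s.country}): non-positive volume in year "
                    f"{year}, week {week}; log outcome undefined"
                )
            rows.append(
                {
                    "t": t,
                    "year": year,
                    "i": 1 if t > 0 else 0,
                    "j": 1 if year == TREATMENT_YEAR else 0,
                    "log_y": np.log(y),
                }
            )
    return pd.DataFrame(rows)


def _design_matrix(design: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    t = design["t"].to_numpy(dtype=float)
    i = design["i"].to_numpy(dtype=float)
    j = design["j"].to_numpy(dtype=float)
    full = {
        "const": np.ones_like(t), "t": t, "t2": t * t,
        "i": i, "i_t": i * t, "i_t2": i * t * t,
        "j": j, "j_t": j * t, "j_t2": j * t * t,
        "ij": i * j, "ij_t": i * j * t, "ij_t2": i * j * t * t,
    }
    return pd.DataFrame({c: full[c] for c in spec.columns})


def fit_rdd(design: pd.DataFrame, spec: ModelSpec) -> RDDFit:
    """OLS fit of the chosen form with classical standard errors."""
    X = _design_matrix(design, spec)
    y = design["log_y"].to_numpy(dtype=float)
    p = X.shape[1]
    if len(y) < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    return RDDFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        cov=res.cov_params(),
        n_obs=len(y),
        df_resid=int(res.df_resid),
        residual_variance=float(res.scale),
    )


def _effect_from_log(a: float, se: float, df: int) -> EffectEstimate:
    tstat = a / se if se > 0 else np.inf * np.sign(a) if a != 0 else 0.0
    p = float(2 * scipy.stats.t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
    return EffectEstimate(
        point=float(np.expm1(a)),
        ci_low=float(np.expm1(a - CI_SE_MULTIPLIER * se)),
        ci_high=float(np.expm1(a + CI_SE_MULTIPLIER * se)),
        p_value=p,
        significant=p < 0.05,
        log_effect=float(a),
        log_se=float(se),
    )


def short_term_effect(fit: RDDFit) -> EffectEstimate:
    """Multiplicative jump at the cutoff: ``e**alpha - 1`` with +/- 2 SE CI."""
    return _effect_from_log(fit.alpha, fit.alpha_se, fit.df_resid)


def counterfactual_gap(fit: RDDFit, t: int) -> GapEstimate:
    """Fitted 2020 curve vs the 2019-based counterfactual at week ``t``.

    Both are mean-response estimates with 95% intervals from the
    coefficient covariance (x.Cov.x' variance of the linear combination);
    ``overlapping`` says whether the two intervals intersect.
    """
    if not 0 < t <= fit.spec.t_max:
        raise ValueError(f"t must lie in (0, {fit.spec.t_max}]")
    f20, se20 = fit.predict_log(t, TREATMENT_YEAR)
    f19, se19 = fit.predict_log(t, BASELINE_YEAR)
    lo20, hi20 = f20 - CI_SE_MULTIPLIER * se20, f20 + CI_SE_MULTIPLIER * se20
    lo19, hi19 = f19 - CI_SE_MULTIPLIER * se19, f19 + CI_SE_MULTIPLIER * se19
    return GapEstimate(
        t=t,
        gap_2020=f20,
        gap_2019=f19,
        ci_2020=(lo20, hi20),
        ci_2019=(lo19, hi19),
        overlapping=not (lo20 > hi19 or lo19 > hi20),
    )


def reversion_time(fit: RDDFit, spec: ModelSpec | None = None) -> ReversionResult:
    """Weeks until the 2020 fit reverts to the 2019 counterfactual.

    Reversion is the smallest t with overlapping 95% intervals at t *and
    every later week* (sustained overlap, so single-week flickers do not
    count; a discrepancy between the first-overlap and sustained-overlap
    answers is logged).  ``never_differed`` if the intervals already
    overlap at t = 1; ``not_reverted`` if they still differ at t_max.
    """
    spec = spec or fit.spec
    overlaps = np.array(
        [counterfactual_gap(fit, t).overlapping for t in range(1, spec.t_max + 1)]
    )
    if overlaps[0]:
        if not overlaps.all():
            logger.info("intervals overlap at t=1 but separate again later")
        return ReversionResult("never_differed")
    sustained = None
    for t in range(2, spec.t_max + 1):
        if overlaps[t - 1 :].all():
            sustained = t
            break
    if sustained is None:
        return ReversionResult("not_reverted")
    first = int(np.nonzero(overlaps)[0][0]) + 1
    if first != sustained:
        logger.info(
            "first overlap at t=%d, sustained overlap only from t=%d", first, sustained
        )
    return ReversionResult("reverted", weeks=sustained)


def long_term_effect(fit: RDDFit, spec: ModelSpec | None = None) -> EffectEstimate:
    """How elevated the fitted outcome remains at ``t_max``.

    The effect is ``exp(fitted log outcome at (t_max, 2020) minus the
    fitted log outcome at (t_max, 2019)) - 1``, with the CI from the
    covariance of the coefficient contrast.
    """
    spec = spec or fit.spec
    c = (
        fit.feature_row(spec.t_max, TREATMENT_YEAR)
        - fit.feature_row(spec.t_max, BASELINE_YEAR)
    ).to_numpy()
    a = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov.to_numpy() @ c))
    return _effect_from_log(a, se, fit.df_resid)


def share_outcome(group: InterestSeries, total_food: InterestSeries) -> InterestSeries:
    """Week-wise share of total food interest allocated to ``group``.

    The resulting series (values in (0, 1]) can be fitted with
    ``outcome="log_share"`` to ask whether a group grew *relative to*
    overall food interest rather than in absolute volume.
    """
    if not group.same_grid(total_food):
        raise ValueError(
            f"{group.label!r} and {total_food.label!r} are on different week grids"
        )
    g = group.data["volume"].to_numpy()
    tot = total_food.data["volume"].to_numpy()
    zero = tot <= 0
    if zero.any():
        row = group.data.iloc[int(np.nonzero(zero)[0][0])]
        raise ValueError(
            f"total food volume is zero in year {int(row['year'])}, "
            f"week {int(row['week'])}"
        )
    if (g > tot).any():
        raise ValueError("group volume exceeds total food volume")
    return group.with_volumes(g / tot, label=f"{group.label}_share")
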