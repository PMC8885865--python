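"""Difference-in-discontinuities fit and its derived quantities."""
import math

import numpy as np
import pandas as pd
import pytest

import dietshift as ds
from dietshift import rdd

from conftest import make_series


def fit_series(s, form="quadratic", cutoff=12, t_min=10, t_max=30):
    spec = ds.ModelSpec(form, t_min, t_max, cutoff)
    return ds.fit_rdd(ds.build_design(s, spec), spec), spec


class TestDesign:
    def test_default_window_has_82_rows(self, flat_series, default_spec):
        design = ds.build_design(flat_series, default_spec)
        assert len(design) == (10 + 30 + 1) * 2 == 82

    def test_indicator_definitions(self, flat_series, default_spec):
        design = ds.build_design(flat_series, default_spec)
        at = lambda t, yr: design[(design["t"] == t) & (design["year"] == yr)].iloc[0]
        row = at(0, 2020)
        assert (row["i"], row["j"]) == (0, 1)  # cutoff week itself untreated
        row = at(5, 2019)
        assert (row["i"], row["j"]) == (1, 0)
        row = at(-3, 2019)
        assert (row["i"], row["j"]) == (0, 0)

    def test_missing_week_is_hard_error(self, flat_series, default_spec):
        holey = ds.InterestSeries(
            "XX", "holey",
            flat_series.data[~((flat_series.data.year == 2020) & (flat_series.data.week == 20))],
        )
        with pytest.raises(ValueError, match="week 20"):
            ds.build_design(holey, default_spec)

    def test_zero_volume_error_names_week(self, flat_series, default_spec):
        df = flat_series.data.copy()
        df.loc[(df.year == 2020) & (df.week == 15), "volume"] = 0.0
        with pytest.raises(ValueError, match="week 15"):
            ds.build_design(ds.InterestSeries("XX", "z", df), default_spec)

    def test_window_must_fit_the_year(self, flat_series):
        with pytest.raises(ValueError, match="grid"):
            ds.build_design(flat_series, ds.ModelSpec("quadratic", 10, 45, 12))


class TestFit:
    def test_identical_years_zero_interaction_block(self, flat_series):
        fit, _ = fit_series(flat_series)
        for name in ("j", "j_t", "j_t2", "ij", "ij_t", "ij_t2"):
            assert abs(fit.params[name]) < 1e-8

    def test_nested_constant_shock_recovered_exactly(self):
        params = ds.SeasonalShockParams(
            noise_sigma=0.0, shock_log_effect=0.5, shock_decay=(0.0, 0.0)
        )
        fit, _ = fit_series(ds.generate_interest_series(params))
        assert fit.alpha == pytest.approx(0.5, abs=1e-8)
        assert abs(fit.params["ij_t"]) < 1e-8
        assert abs(fit.params["ij_t2"]) < 1e-8
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-16)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        s = ds.generate_interest_series(ds.SeasonalShockParams(noise_sigma=0.2, seed=1))
        fit, spec = fit_series(s)
        design = ds.build_design(s, spec)
        X = rdd._design_matrix(design, spec).to_numpy(dtype=np.longdouble)
        y = design["log_y"].to_numpy(dtype=np.longdouble)
        beta = np.linalg.solve(
            (X.T @ X).astype(float), (X.T @ y).astype(float)
        )
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_constant_form_is_difference_in_means(self):
        """alpha in the constant form equals the hand-computed 2x2 contrast
        of mean log outcomes (treated vs untreated, 2020 vs 2019)."""
        s = ds.generate_interest_series(ds.SeasonalShockParams(noise_sigma=0.3, seed=8))
        fit, spec = fit_series(s, form="constant")
        design = ds.build_design(s, spec)
        mean = lambda i, j: design[(design["i"] == i) & (design["j"] == j)]["log_y"].mean()
        oracle = (mean(1, 1) - mean(0, 1)) - (mean(1, 0) - mean(0, 0))
        assert fit.alpha == pytest.approx(oracle, abs=1e-10)

    def test_year_swap_negates_interaction_block(self):
        """Relabeling the years flips the sign of the 2020-interaction terms."""
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.0, shock_log_effect=0.4,
                                   shock_decay=(-0.02, 0.0))
        )
        fit, spec = fit_series(s)
        swapped = s.data.copy()
        swapped["year"] = swapped["year"].map({2019: 2020, 2020: 2019})
        fit_sw, _ = fit_series(ds.InterestSeries("XX", "sw", swapped), cutoff=12)
        for name in ("j", "j_t", "j_t2", "ij", "ij_t", "ij_t2"):
            assert fit_sw.params[name] == pytest.approx(-fit.params[name], abs=1e-8)

    def test_rank_deficiency_rejected(self, flat_series, default_spec):
        design = ds.build_design(flat_series, default_spec)
        design["t"] = 0  # collapses t columns onto the intercept
        with pytest.raises(ValueError, match="rank"):
            ds.fit_rdd(design, default_spec)


class TestShortTermEffect:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.0, 0.0), (math.log(2), 1.0), (math.log(1.5), 0.5)],
    )
    def test_analytic_conversion(self, alpha, expected):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.0, shock_log_effect=alpha,
                                   shock_decay=(0.0, 0.0))
        )
        fit, _ = fit_series(s)
        est = ds.short_term_effect(fit)
        assert est.point == pytest.approx(expected, abs=1e-9)

    def test_ci_and_significance(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.1, shock_log_effect=1.0, seed=3)
        )
        fit, _ = fit_series(s)
        est = ds.short_term_effect(fit)
        assert est.ci_low < est.point < est.ci_high
        assert est.ci_low == pytest.approx(math.expm1(est.log_effect - 2 * est.log_se))
        assert est.significant and est.p_value < 0.05


class TestCounterfactualGap:
    def test_identical_years_overlap_everywhere(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.05, shock_log_effect=0.0,
                                   shock_decay=(0.0, 0.0), seed=2)
        )
        fit, spec = fit_series(s)
        for t in (1, 10, 30):
            gap = ds.counterfactual_gap(fit, t)
            assert gap.overlapping

    def test_interval_variance_matches_quadratic_form_oracle(self):
        s = ds.generate_interest_series(ds.SeasonalShockParams(noise_sigma=0.2, seed=5))
        fit, spec = fit_series(s)
        design = ds.build_design(s, spec)
        X = rdd._design_matrix(design, spec).to_numpy()
        y = design["log_y"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        cov = sigma2 * XtX_inv
        for t in (1, 15, 30):
            gap = ds.counterfactual_gap(fit, t)
            x20 = fit.feature_row(t, 2020).to_numpy()
            se = math.sqrt(x20 @ cov @ x20)
            assert gap.ci_2020[0] == pytest.approx(x20 @ beta - 2 * se, abs=1e-8)
            assert gap.ci_2020[1] == pytest.approx(x20 @ beta + 2 * se, abs=1e-8)

    def test_large_shock_not_overlapping_at_t1(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.02, shock_log_effect=2.0,
                                   shock_decay=(-0.01, 0.0), seed=6)
        )
        fit, _ = fit_series(s)
        assert not ds.counterfactual_gap(fit, 1).overlapping

    def test_t_outside_window_rejected(self, flat_series):
        fit, _ = fit_series(flat_series)
        with pytest.raises(ValueError):
            ds.counterfactual_gap(fit, 0)
        with pytest.raises(ValueError):
            ds.counterfactual_gap(fit, 31)


class TestReversionAndLongTerm:
    def test_identical_years_never_differed(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.05, shock_log_effect=0.0,
                                   shock_decay=(0.0, 0.0), seed=7)
        )
        fit, _ = fit_series(s)
        assert ds.reversion_time(fit).status == "never_differed"

    def test_permanent_shock_not_reverted(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.02, shock_log_effect=1.5,
                                   shock_decay=(0.0, 0.0), seed=9)
        )
        fit, _ = fit_series(s)
        assert ds.reversion_time(fit).status == "not_reverted"

    def test_long_term_identical_years_zero(self, flat_series):
        fit, _ = fit_series(flat_series)
        assert ds.long_term_effect(fit).point == pytest.approx(0.0, abs=1e-9)

    def test_long_term_permanent_shock_analytic(self):
        s = ds.generate_interest_series(
            ds.SeasonalShockParams(noise_sigma=0.0, shock_log_effect=0.3,
                                   shock_decay=(0.0, 0.0))
        )
        fit, _ = fit_series(s)
        est = ds.long_term_effect(fit)
        assert est.point == pytest.approx(math.expm1(0.3), abs=1e-9)

    def test_long_term_variance_matches_contrast_oracle(self):
        s = ds.generate_interest_series(ds.SeasonalShockParams(noise_sigma=0.15, seed=4))
        fit, spec = fit_series(s)
        c = (fit.feature_row(30, 2020) - fit.feature_row(30, 2019)).to_numpy()
        se_oracle = math.sqrt(c @ fit.cov.to_numpy() @ c)
        est = ds.long_term_effect(fit)
        assert est.log_se == pytest.approx(se_oracle, rel=1e-12)
        assert est.ci_high == pytest.approx(
            math.expm1(est.log_effect + 2 * se_oracle), rel=1e-12
        )


class TestShareOutcome:
    def test_group_equal_total_gives_unit_share(self):
        g = make_series([10, 20, 30])
        assert (ds.share_outcome(g, g).data["volume"] == 1.0).all()

    def test_simple_shares(self):
        g = make_series([10, 20])
        tot = make_series([100, 100], label="total")
        np.testing.assert_allclose(
            ds.share_outcome(g, tot).data["volume"], [0.10, 0.20]
        )

    def test_partition_shares_sum_to_one(self):
        rng = np.random.default_rng(12)
        parts = [make_series(rng.uniform(1, 50, 10), label=f"p{i}") for i in range(4)]
        total = parts[0].with_volumes(
            sum(p.data["volume"].to_numpy() for p in parts), label="total"
        )
        share_sum = sum(
            ds.share_outcome(p, total).data["volume"].to_numpy() for p in parts
        )
        np.testing.assert_allclose(share_sum, 1.0, rtol=1e-12)

    def test_zero_total_rejected(self):
        g = make_series([0, 1])
        tot = make_series([0, 2], label="total")
        with pytest.raises(ValueError, match="zero"):
            ds.share_outcome(g, tot)
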