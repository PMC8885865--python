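"""Generator properties: symmetry, determinism, noise calibration, truth."""
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

import dietshift as ds
from dietshift.synthetic import (
    mobility_profile,
    true_threshold_crossing_day,
)


class TestInterestGenerator:
    def test_no_shock_no_noise_years_identical(self, flat_series):
        """Without a shock the two years share the seasonal component exactly."""
        v2019 = flat_series.volumes(2019)
        v2020 = flat_series.volumes(2020)
        assert len(v2019) == len(v2020) == 52
        np.testing.assert_array_equal(v2019.to_numpy(), v2020.to_numpy())

    def test_constant_shock_doubles_post_cutoff_weeks(self):
        params = ds.SeasonalShockParams(
            noise_sigma=0.0, shock_log_effect=math.log(2), shock_decay=(0.0, 0.0)
        )
        s = ds.generate_interest_series(params)
        ratio = s.volumes(2020) / s.volumes(2019)
        post = ratio.index > params.cutoff_week_of_year
        np.testing.assert_allclose(ratio[post], 2.0, rtol=1e-12)
        np.testing.assert_allclose(ratio[~post], 1.0, rtol=1e-12)

    def test_seeded_determinism(self):
        params = ds.SeasonalShockParams(noise_sigma=0.3, seed=17)
        a = ds.generate_interest_series(params)
        b = ds.generate_interest_series(params)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = ds.generate_interest_series(ds.SeasonalShockParams(noise_sigma=0.3, seed=18))
        assert not np.array_equal(a.data["volume"], c.data["volume"])

    def test_holiday_bumps_in_both_years(self):
        params = ds.SeasonalShockParams(
            noise_sigma=0.0, shock_log_effect=0.0, shock_decay=(0.0, 0.0),
            holiday_weeks=(51, 52), holiday_multiplier=1.5,
        )
        s = ds.generate_interest_series(params)
        for year in (2019, 2020):
            v = s.volumes(year)
            assert v[51] == pytest.approx(1.5 * v[50] * math.exp(params.trend_per_week))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ds.SeasonalShockParams(baseline_level=0.0)
        with pytest.raises(ValueError):
            ds.SeasonalShockParams(noise_sigma=-0.1)
        with pytest.raises(ValueError):
            ds.SeasonalShockParams(holiday_weeks=(0,))


class TestMobilityGenerator:
    def test_zero_before_onset_and_exact_peak(self):
        params = ds.MobilityShockParams(peak_severity=30.0, noise_sigma=0.0)
        m = ds.generate_mobility_series(params)
        pre = m.values[m.values.index <= pd.Timestamp(params.onset_day)]
        assert (pre == 0.0).all()
        assert m.values.max() == pytest.approx(30.0, abs=0)

    def test_monotone_rise_and_recovery(self):
        params = ds.MobilityShockParams(peak_severity=25.0, noise_sigma=0.0)
        m = ds.generate_mobility_series(params)
        v = m.values
        onset = pd.Timestamp(params.onset_day)
        rise = v[(v.index > onset) & (v.index <= onset + pd.Timedelta(days=params.rise_days))]
        assert (np.diff(rise.to_numpy()) >= 0).all()
        rec_start = onset + pd.Timedelta(days=params.rise_days + params.plateau_days)
        rec = v[(v.index > rec_start) & (v.index <= rec_start + pd.Timedelta(days=params.recovery_days))]
        assert (np.diff(rec.to_numpy()) <= 0).all()
        assert v.iloc[-1] == pytest.approx(0.0)

    def test_noise_sd_calibrated_on_pre_onset_days(self):
        """Pre-onset residuals are pure noise: sample SD ~= sigma within 3 SE."""
        sigma = 2.0
        params = ds.MobilityShockParams(noise_sigma=sigma, seed=5)
        m = ds.generate_mobility_series(params)
        pre = m.values[m.values.index < pd.Timestamp(params.onset_day)].to_numpy()
        n = len(pre)
        assert n >= 40
        sd = pre.std(ddof=1)
        se_of_sd = sigma / math.sqrt(2 * (n - 1))
        assert abs(sd - sigma) < 3 * se_of_sd

    def test_second_wave_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ds.MobilityShockParams(
                onset_day=date(2020, 3, 15),
                second_onset_day=date(2020, 5, 1),
                second_peak_severity=20.0,
            )

    def test_second_wave_rises_after_first(self):
        params = ds.MobilityShockParams(
            peak_severity=30.0,
            noise_sigma=0.0,
            second_onset_day=date(2020, 10, 15),
            second_peak_severity=18.0,
        )
        m = ds.generate_mobility_series(params)
        assert m.values.loc["2020-12-31"] == pytest.approx(18.0)
        assert m.values.loc["2020-09-15"] == pytest.approx(0.0)

    def test_true_crossing_day_is_first_threshold_hit(self):
        params = ds.MobilityShockParams(peak_severity=30.0, noise_sigma=0.0)
        day = true_threshold_crossing_day(params, 10.0)
        dates = pd.date_range("2020-02-01", "2020-12-31", freq="D")
        v = pd.Series(mobility_profile(params, dates), index=dates)
        assert v[day] >= 10.0
        assert (v[v.index < day] < 10.0).all()


class TestCountryPanel:
    def test_zero_dose_slope_gives_zero_truth(self):
        panel = ds.generate_country_panel(3, dose_slope=0.0, seed=1)
        for truth in panel.truth.values():
            base = [a for k, a in truth.alpha.items() if k != "total_food"]
            assert all(a == 0.0 for a in base)

    def test_truth_strictly_increasing_in_severity(self):
        panel = ds.generate_country_panel(
            6, severity_range=(10.1, 31.6), dose_slope=2.0, seed=0
        )
        alphas = [panel.truth[c].alpha["household_home"] for c in panel.countries]
        sev = [panel.truth[c].severity for c in panel.countries]
        assert sev == sorted(sev)
        assert all(b > a for a, b in zip(alphas, alphas[1:]))

    def test_degenerate_severity_range_rejected(self):
        with pytest.raises(ValueError, match="width"):
            ds.generate_country_panel(4, severity_range=(20.0, 20.0))

    def test_every_country_has_both_records_and_recorded_truth(self):
        panel = ds.generate_country_panel(3, severity_range=(10.0, 30.0), seed=2)
        expected = np.linspace(10.0, 30.0, 3)
        for c, sev in zip(panel.countries, expected):
            assert c in panel.interest and c in panel.mobility
            assert panel.truth[c].severity == sev  # truth matches inputs exactly

    def test_noiseless_panel_fit_recovers_truth_exactly(self):
        """End-to-end: fitting a noiseless country recovers its true alpha."""
        panel = ds.generate_country_panel(
            3, noise_sigma=0.0, mobility_noise_sigma=0.0, seed=4
        )
        c = panel.countries[-1]
        s = panel.interest[c]["household_home"]
        cp = ds.detect_changepoints(panel.mobility[c])
        spec = ds.ModelSpec("quadratic", 10, 30, cp.cutoff_week)
        fit = ds.fit_rdd(ds.build_design(s, spec), spec)
        assert fit.alpha == pytest.approx(panel.truth[c].alpha["household_home"], abs=1e-8)
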