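"""Generator tests: radiation helpers, truth statistics, member perturbation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greencast import (
    ClimateConfig,
    DomainError,
    extraterrestrial_radiation,
    generate_truth,
    markov_wet_fraction,
    perturb_members,
    prescott_radiation,
)
from greencast.synthetic_weather import SEASON_DAYS


def reference_ra(doy: int, latitude_deg: float) -> float:
    """Independent step-by-step solar-geometry oracle (scalar, degrees-based)."""
    gsc = 0.0820
    phi = latitude_deg * math.pi / 180.0
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    delta = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    ws = math.acos(-math.tan(phi) * math.tan(delta))
    return (
        24 * 60 / math.pi * gsc * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )


class TestExtraterrestrialRadiation:
    def test_southern_hemisphere_september_value(self):
        # 3 September at 20 deg S: canonical worked value ~32.2 MJ/m2/day
        ra = extraterrestrial_radiation(246, -20.0)
        assert ra == pytest.approx(32.2, abs=0.05)
        assert ra == pytest.approx(reference_ra(246, -20.0), rel=1e-12)

    @pytest.mark.parametrize("doy,lat", [(1, 45.0), (100, -60.0), (200, 0.0), (366, 65.0)])
    def test_matches_independent_oracle(self, doy, lat):
        assert extraterrestrial_radiation(doy, lat) == pytest.approx(
            reference_ra(doy, lat), rel=1e-12
        )

    def test_equinox_hemispheric_symmetry(self):
        # declination is ~0 near the March equinox, so the hemispheres agree
        assert extraterrestrial_radiation(80, 45.0) == pytest.approx(
            extraterrestrial_radiation(80, -45.0), rel=0.02
        )

    def test_summer_exceeds_winter_in_north(self):
        assert extraterrestrial_radiation(172, 45.0) > extraterrestrial_radiation(355, 45.0)

    def test_positive_in_allowed_band(self):
        doy = np.arange(1, 367)
        assert np.all(extraterrestrial_radiation(doy, 60.0) > 0)
        assert np.all(extraterrestrial_radiation(doy, -60.0) > 0)

    @pytest.mark.parametrize("lat", [-80.0, 66.0, 90.0])
    def test_polar_latitudes_rejected(self, lat):
        with pytest.raises(DomainError):
            extraterrestrial_radiation(100, lat)

    def test_day_of_year_bounds(self):
        with pytest.raises(DomainError):
            extraterrestrial_radiation(0, 45.0)
        with pytest.raises(DomainError):
            extraterrestrial_radiation(367, 45.0)


class TestPrescottRadiation:
    @pytest.mark.parametrize(
        "frac,ra,expected",
        [(0.0, 30.0, 7.5), (1.0, 30.0, 22.5), (0.5, 40.0, 20.0)],
    )
    def test_linear_in_sunshine_fraction(self, frac, ra, expected):
        assert prescott_radiation(frac, ra, a=0.25, b=0.50) == pytest.approx(expected)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            prescott_radiation(1.2, 30.0)
        with pytest.raises(DomainError):
            prescott_radiation(-0.1, 30.0)

    def test_coefficient_constraint(self):
        with pytest.raises(DomainError):
            prescott_radiation(0.5, 30.0, a=0.6, b=0.6)


class TestGenerateTruth:
    def test_same_seed_reproduces_identical_series(self, climate):
        a = generate_truth(climate, 2010, 42)
        b = generate_truth(climate, 2010, 42)
        for name in ("tmax", "tmin", "rhum", "wind", "srad", "precip"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        assert a.dates.equals(b.dates)

    def test_different_seeds_differ(self, climate):
        a = generate_truth(climate, 2010, 1)
        b = generate_truth(climate, 2010, 2)
        assert not np.array_equal(a.tmax, b.tmax)

    def test_window_is_march_through_october_first(self, climate):
        s = generate_truth(climate, 2012, 0)  # leap year: window length unchanged
        assert len(s) == SEASON_DAYS == 215
        assert s.dates[0].month == 3 and s.dates[0].day == 1
        assert s.dates[-1].month == 10 and s.dates[-1].day == 1

    def test_degenerate_config_gives_constant_temperatures(self, quiet_climate):
        s = generate_truth(quiet_climate, 2010, 5)
        np.testing.assert_allclose(s.tmax, s.tmax[0])
        np.testing.assert_allclose(s.tmin, s.tmin[0])
        assert s.tmax[0] - s.tmin[0] == pytest.approx(quiet_climate.diurnal_range)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), year=st.integers(2000, 2030))
    def test_physical_bounds_hold(self, seed, year):
        config = ClimateConfig()
        s = generate_truth(config, year, seed)
        assert np.all(s.tmax >= s.tmin)
        assert np.all(s.precip >= 0)
        assert np.all((s.rhum >= 0) & (s.rhum <= 100))
        assert np.all(s.srad >= 0) and np.all(s.wind >= 0)

    def test_wet_day_frequency_matches_markov_stationary_law(self, climate):
        # ~10,750 generated days across 50 seasons
        wet = np.concatenate(
            [generate_truth(climate, 2000 + i % 10, i).precip > 0 for i in range(50)]
        )
        expected = markov_wet_fraction(climate.p01, climate.p11)
        assert abs(wet.mean() - expected) < 0.02

    def test_mean_season_total_matches_analytic_expectation(self, climate):
        totals = [generate_truth(climate, 2010, seed).precip.sum() for seed in range(200)]
        expected = (
            SEASON_DAYS
            * markov_wet_fraction(climate.p01, climate.p11)
            * climate.precip_shape
            * climate.precip_scale
        )
        assert np.mean(totals) == pytest.approx(expected, rel=0.05)


class TestPerturbMembers:
    def test_zero_bias_zero_inflation_members_equal_truth(self, climate):
        config = climate.with_scenario(temp_bias=0.0, precip_bias=1.0, member_inflation=0.0)
        truth = generate_truth(config, 2010, 3)
        members, control = perturb_members(truth, 5, config, 9)
        for series in [control, *members]:
            np.testing.assert_array_equal(series.tmax, truth.tmax)
            np.testing.assert_array_equal(series.precip, truth.precip)

    def test_pure_temperature_shift(self, climate):
        config = climate.with_scenario(temp_bias=1.0, member_inflation=0.0)
        truth = generate_truth(config, 2010, 3)
        members, control = perturb_members(truth, 3, config, 9)
        np.testing.assert_allclose(members[0].tmax - truth.tmax, 1.0)
        np.testing.assert_allclose(control.tmin - truth.tmin, 1.0)

    def test_multiplicative_precip_bias_recovered_over_members(self, climate):
        # Monte Carlo: member-mean season totals over many seasons recover
        # the configured multiplicative bias against the truth totals
        config = climate.with_scenario(precip_bias=1.2, member_inflation=1.0)
        member_means, truth_totals = [], []
        for seed in range(20):
            truth = generate_truth(config, 2010, seed)
            members, _ = perturb_members(truth, 50, config, 900 + seed)
            member_means.append(np.mean([m.precip.sum() for m in members]))
            truth_totals.append(truth.precip.sum())
        ratio = np.sum(member_means) / np.sum(truth_totals)
        assert ratio == pytest.approx(1.2, abs=0.05)

    def test_members_distinct_under_inflation(self, climate):
        truth = generate_truth(climate, 2010, 3)
        members, _ = perturb_members(truth, 5, climate, 9)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                assert not np.array_equal(members[i].tmax, members[j].tmax)

    def test_member_streams_stable_as_ensemble_grows(self, climate):
        truth = generate_truth(climate, 2010, 3)
        small, _ = perturb_members(truth, 5, climate, 9)
        large, _ = perturb_members(truth, 12, climate, 9)
        for k in range(5):
            np.testing.assert_array_equal(small[k].tmax, large[k].tmax)
            np.testing.assert_array_equal(small[k].precip, large[k].precip)

    def test_perturbed_members_satisfy_invariants(self, climate):
        config = climate.with_scenario(temp_bias=-2.0, precip_bias=0.7, member_inflation=2.0)
        truth = generate_truth(config, 2010, 3)
        members, control = perturb_members(truth, 8, config, 1)
        for series in [control, *members]:
            series.validate()

    def test_fewer_than_two_members_rejected(self, climate):
        truth = generate_truth(climate, 2010, 3)
        with pytest.raises(DomainError):
            perturb_members(truth, 1, climate, 9)


class TestClimateConfig:
    def test_member_count_defaults_ramp_from_10_to_50(self):
        config = ClimateConfig()
        assert config.n_members(2006) == 10
        assert config.n_members(2014) == 50
        assert config.n_members(2010) == 30

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p01": 1.5},
            {"precip_shape": 0.0},
            {"precip_bias": 0.0},
            {"member_inflation": -1.0},
            {"temp_noise_ar1": 1.0},
            {"members_per_year": {2010: 1}},
            {"latitude": 80.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            ClimateConfig(**kwargs)
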