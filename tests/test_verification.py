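"""RMSE/spread decomposition, skill criteria and multi-year summaries."""

import math

import numpy as np
import pytest

from greencast import (
    DomainError,
    EnsembleOutcome,
    multi_year_summary,
    pielke_skill,
    year_rmse,
    year_spread,
    year_stats,
)


def outcome(members, observed, control=None, year=2010, variable="yield"):
    if control is None:
        control = float(np.mean(members))
    return EnsembleOutcome(
        year=year, site="s", crop="c", variable=variable,
        members=np.asarray(members, float), control=control, observed=observed,
    )


class TestYearRmse:
    def test_hand_arithmetic(self):
        assert year_rmse(outcome([1, 2, 3], 2.0)) == pytest.approx(math.sqrt(2 / 3))
        assert year_rmse(outcome([2, 4, 6], 3.0)) == pytest.approx(math.sqrt(11 / 3))

    def test_perfect_forecast_scores_zero(self):
        assert year_rmse(outcome([2, 2, 2], 2.0)) == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(DomainError):
            outcome([1.0], 1.0)


class TestYearSpread:
    def test_hand_arithmetic(self):
        assert year_spread(outcome([2, 4, 6], 0.0)) == pytest.approx(math.sqrt(8 / 3))

    def test_constant_members_have_no_dispersion(self):
        assert year_spread(outcome([3, 3, 3], 1.0)) == 0.0

    def test_unbiased_ensemble_has_equal_rmse_and_spread(self):
        # ensemble mean equals the observation: the ideal-ensemble property
        o = outcome([1, 2, 3], 2.0)
        assert year_rmse(o) == pytest.approx(year_spread(o)) == pytest.approx(0.8165, abs=1e-4)


class TestDecomposition:
    def test_exact_identity_and_ordering_on_random_ensembles(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(2, 51)
            members = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 20), size=n)
            obs = rng.normal(0, 30)
            o = outcome(members, obs)
            rmse, sprd = year_rmse(o), year_spread(o)
            ea_err = o.ensemble_average - obs
            assert rmse**2 == pytest.approx(sprd**2 + ea_err**2, rel=1e-9)
            assert rmse >= sprd - 1e-12

    def test_member_permutation_and_duplication_invariance(self):
        members = np.array([1.0, 4.0, 2.5, 7.0])
        o = outcome(members, 3.0)
        o_perm = outcome(members[::-1], 3.0)
        o_dup = outcome(np.tile(members, 2), 3.0)
        assert year_rmse(o) == pytest.approx(year_rmse(o_perm))
        assert year_rmse(o) == pytest.approx(year_rmse(o_dup))
        assert year_spread(o) == pytest.approx(year_spread(o_dup))

    def test_calibrated_ensemble_spread_skill_relation(self):
        # members and observation exchangeable draws: the mean squared error of
        # the ensemble mean matches (N+1)/N times the mean sample spread^2,
        # and the member-based mean rmse^2 matches 2N/(N-1) times the mean
        # population spread^2
        rng = np.random.default_rng(7)
        n, reps = 10, 500
        ea_err2, sprd2_sample, rmse2, sprd2_pop = [], [], [], []
        for _ in range(reps):
            members = rng.normal(size=n)
            obs = rng.normal()
            o = outcome(members, obs)
            ea_err2.append((o.ensemble_average - obs) ** 2)
            sprd2_sample.append(year_spread(o, ddof=1) ** 2)
            rmse2.append(year_rmse(o) ** 2)
            sprd2_pop.append(year_spread(o) ** 2)
        assert np.mean(ea_err2) == pytest.approx(
            (n + 1) / n * np.mean(sprd2_sample), rel=0.15
        )
        assert np.mean(rmse2) == pytest.approx(
            2 * n / (n - 1) * np.mean(sprd2_pop), rel=0.15
        )


class TestPielkeSkill:
    def test_error_below_observed_variability(self):
        skill_a, _ = pielke_skill(0.5, 1.0, 1.0)
        assert skill_a

    def test_matching_variability_always_close(self):
        for band in (1.0, 1.5, 3.0):
            _, skill_b = pielke_skill(2.0, 1.0, 1.0, closeness_band=band)
            assert skill_b

    def test_underdispersed_simulation_fails_closeness(self):
        _, skill_b = pielke_skill(0.1, 0.4, 1.0, closeness_band=2.0)
        assert not skill_b

    def test_zero_observed_variability_rejected(self):
        with pytest.raises(DomainError):
            pielke_skill(0.5, 0.5, 0.0)

    def test_year_stats_carries_skill_flags(self):
        stats = year_stats(outcome([1, 2, 3], 2.0), sigma_obs=1.0, closeness_band=2.0)
        assert stats.skill_a is True and stats.skill_b is True
        assert year_stats(outcome([1, 2, 3], 2.0)).skill_a is None


class TestMultiYearSummary:
    def two_year_outcomes(self, ea_offset=0.0, cr_offset=0.0):
        outs = []
        for year, ob in [(2010, 2.0), (2011, 4.0)]:
            members = np.array([ob + ea_offset - 1, ob + ea_offset + 1])
            outs.append(
                EnsembleOutcome(
                    year=year, site="s", crop="c", variable="yield",
                    members=members, control=ob + cr_offset, observed=ob,
                )
            )
        return outs

    def test_sample_convention_statistics(self):
        summary = multi_year_summary(self.two_year_outcomes())
        ob = summary.datasets["OB"]
        assert ob.mean == pytest.approx(3.0)
        assert ob.sigma == pytest.approx(1.0 * math.sqrt(2))
        # spec'd hand case {2,4}: mean 3, sample sigma sqrt(2), cv sqrt(2)/3
        assert ob.cv == pytest.approx(ob.sigma / 3.0)

    def test_perfect_ensemble_average_has_zero_cross_year_rmse(self):
        summary = multi_year_summary(self.two_year_outcomes(ea_offset=0.0))
        assert summary.rmse_ea == pytest.approx(0.0)

    def test_constant_control_offset_gives_unit_rmse(self):
        summary = multi_year_summary(self.two_year_outcomes(cr_offset=1.0))
        assert summary.rmse_cr == pytest.approx(1.0)

    def test_single_year_rejected(self):
        with pytest.raises(DomainError):
            multi_year_summary(self.two_year_outcomes()[:1])

    def test_mixed_groups_rejected(self):
        outs = self.two_year_outcomes()
        outs[1].variable = "et"
        with pytest.raises(DomainError):
            multi_year_summary(outs)
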