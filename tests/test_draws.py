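"""Posterior draws: degenerate limits, determinism, distributional agreement,
and the YPLL-75 composite against a brute-force oracle."""

import numpy as np
import pytest
from scipy import stats

import countyrank as cr
from countyrank.draws import AgeSchedule, PosteriorDraws, YPLL_WEIGHTS

from _oracles import ypll_bruteforce


class TestDrawPosterior:
    def test_zero_covariance_reproduces_eb_point_prediction(self, longitudinal_fit):
        _, _, fit = longitudinal_fit
        draws = cr.draw_posterior(fit, 5, seed=1, zero_covariance=True)["mortality"]
        eta = (
            fit.fixed[0]
            + fit.eb_mean_state[fit.county_state, 0]
            + fit.eb_mean_county[:, 0]
        )
        expected = np.exp(eta)
        assert np.allclose(draws.values, expected[None, :], rtol=1e-12)

    def test_seed_determinism(self, longitudinal_fit):
        _, _, fit = longitudinal_fit
        a = cr.draw_posterior(fit, 50, seed=3)["mortality"]
        b = cr.draw_posterior(fit, 50, seed=3)["mortality"]
        c = cr.draw_posterior(fit, 50, seed=4)["mortality"]
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_single_draw_rejected(self, longitudinal_fit):
        _, _, fit = longitudinal_fit
        with pytest.raises(ValueError):
            cr.draw_posterior(fit, 1, seed=0)

    def test_county_mean_matches_lognormal_moment(self, longitudinal_fit):
        # log-rate draws are Gaussian with assembled mean m and variance v, so
        # the natural-scale mean must be exp(m + v/2) within Monte-Carlo error
        _, _, fit = longitudinal_fit
        D = 10_000
        draws = cr.draw_posterior(fit, D, seed=7)["mortality"].values
        cs = fit.county_state
        m = (
            fit.fixed[0]
            + fit.eb_mean_state[cs, 0]
            + fit.eb_mean_county[:, 0]
        )
        v = (
            fit.fixed_cov[0, 0]
            + fit.eb_cov_state[cs, 0, 0]
            + fit.eb_cov_county[:, 0, 0]
        )
        analytic = np.exp(m + v / 2)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(D)
        z = np.abs(draws.mean(axis=0) - analytic) / mc_se
        assert np.quantile(z, 0.95) < 3.0
        assert z.max() < 5.0

    def test_log_rate_draws_gaussian(self, longitudinal_fit):
        # Kolmogorov-Smirnov sanity check of one county's log-rate draws
        _, _, fit = longitudinal_fit
        D = 10_000
        draws = cr.draw_posterior(fit, D, seed=11)["mortality"].values
        i = 3
        m = (
            fit.fixed[0]
            + fit.eb_mean_state[fit.county_state[i], 0]
            + fit.eb_mean_county[i, 0]
        )
        v = (
            fit.fixed_cov[0, 0]
            + fit.eb_cov_state[fit.county_state[i], 0, 0]
            + fit.eb_cov_county[i, 0, 0]
        )
        stat = stats.kstest(np.log(draws[:, i]), "norm", args=(m, np.sqrt(v)))
        assert stat.pvalue > 0.001

    def test_cross_county_independence_with_zero_state_variance(self):
        # with no state variance, counties in different states co-move only
        # through the shared fixed effect
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.05, sigma2_state=0.0,
                               n_states=10, counties_per_state=5,
                               pop_range=(1e4, 1e5))
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=19)
        fit = cr.fit_cross_sectional(panel, "poisson")
        D = 4000
        draws = np.log(cr.draw_posterior(fit, D, seed=2)["mortality"].values)
        # counties 0 and 30 live in different states
        c01 = np.cov(draws[:, 0], draws[:, 30])[0, 1]
        expected = fit.fixed_cov[0, 0] + fit.eb_cov_state[
            fit.county_state[0], 0, 0
        ] * 0  # state variance ~ 0
        se = np.sqrt(
            (np.var(draws[:, 0]) * np.var(draws[:, 30]) + c01**2) / D
        )
        assert abs(c01 - fit.fixed_cov[0, 0]) < 4 * se

    def test_bivariate_fit_yields_two_measures(self, rng):
        p = cr.GeneratorParams(
            alpha=1.24, beta=-0.07, sigma2_county=0.038, tau2_county=0.038,
            rho_county=-0.313, sigma2_state=0.017, tau2_state=0.002,
            n_states=8, counties_per_state=8,
        )
        panel, _ = cr.simulate_survey_means(p, seed=33)
        fit = cr.fit_joint_bivariate(
            panel, "normal_known_variance",
            measure_labels=("physical_days", "mental_days"),
        )
        out = cr.draw_posterior(fit, 100, seed=5)
        assert set(out) == {"physical_days", "mental_days"}
        for d in out.values():
            assert d.values.shape == (100, panel.hierarchy.n_counties)
            assert (d.values > 0).all()


class TestPosteriorDrawsContainer:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            PosteriorDraws(
                values=np.array([[1.0, np.inf]]),
                counties=(("S", "a"), ("S", "b")),
                measure_name="x",
            )

    def test_roster_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PosteriorDraws(
                values=np.ones((3, 2)),
                counties=(("S", "a"),),
                measure_name="x",
            )


class TestAgeSchedule:
    def test_weights_must_decrease(self):
        counties = (("S", "a"),)
        pops = np.ones((1, 9))
        bad = YPLL_WEIGHTS.copy()
        bad[3] = bad[2]
        with pytest.raises(ValueError):
            AgeSchedule(counties=counties, populations=pops, weights=bad)

    def test_from_panel(self):
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.0, sigma2_state=0.0,
                               n_states=2, counties_per_state=3,
                               beta=tuple([0.5] * 8), tau2_state=tuple([0.0] * 8),
                               tau2_county=tuple([0.0] * 8))
        panel, _ = cr.simulate_mortality_panel(
            p, times=None, ages=tuple(range(1, 10)), seed=1
        )
        sched = AgeSchedule.from_panel(panel)
        assert sched.populations.shape == (6, 9)
        assert (sched.populations > 0).all()


def _random_age_draws(rng, D, C, roster):
    return [
        PosteriorDraws(
            values=rng.uniform(1e-5, 0.05, size=(D, C)),
            counties=roster,
            measure_name=f"age_{a}",
        )
        for a in range(1, 10)
    ]


class TestYPLL:
    def test_zero_rates_give_zero(self):
        roster = (("S", "a"), ("S", "b"))
        draws = [
            PosteriorDraws(np.zeros((3, 2)), roster, f"age_{a}")
            for a in range(1, 10)
        ]
        sched = AgeSchedule(counties=roster, populations=np.ones((2, 9)))
        out = cr.ypll75(draws, sched)
        assert np.all(out.values == 0.0)

    def test_single_group_arithmetic(self):
        # all population in ages 65-74 (weight 5), rate 0.02:
        # 1e5 * 0.02 * 10000 * 5 / 10000 = 10000 per 100,000
        roster = (("S", "a"),)
        draws = [
            PosteriorDraws(
                np.full((4, 1), 0.02 if a == 9 else 0.0), roster, f"age_{a}"
            )
            for a in range(1, 10)
        ]
        pops = np.zeros((1, 9))
        pops[0, 8] = 10_000
        # keep other groups nominally populated to satisfy positivity of total
        sched = AgeSchedule(counties=roster, populations=pops)
        out = cr.ypll75(draws, sched)
        assert np.allclose(out.values, 10_000.0)

    def test_matches_bruteforce_oracle(self, rng):
        D, C = 20, 7
        roster = tuple(("S01", f"C{i:03d}") for i in range(C))
        draws = _random_age_draws(rng, D, C, roster)
        pops = rng.integers(50, 20_000, size=(C, 9)).astype(float)
        sched = AgeSchedule(counties=roster, populations=pops)
        out = cr.ypll75(draws, sched)
        expected = ypll_bruteforce(
            [d.values for d in draws], pops, YPLL_WEIGHTS
        )
        assert np.abs(out.values - expected).max() < 1e-9

    def test_monotone_in_each_age_rate(self, rng):
        D, C = 5, 3
        roster = tuple(("S01", f"C{i:03d}") for i in range(C))
        draws = _random_age_draws(rng, D, C, roster)
        pops = rng.integers(100, 10_000, size=(C, 9)).astype(float)
        sched = AgeSchedule(counties=roster, populations=pops)
        base = cr.ypll75(draws, sched).values
        for a in range(9):
            bumped = [
                PosteriorDraws(
                    d.values + (0.01 if i == a else 0.0), roster, d.measure_name
                )
                for i, d in enumerate(draws)
            ]
            out = cr.ypll75(bumped, sched).values
            assert np.all(out > base)

    def test_roster_mismatch_rejected(self, rng):
        roster = (("S", "a"), ("S", "b"))
        other = (("S", "a"), ("S", "c"))
        draws = _random_age_draws(rng, 3, 2, roster)
        sched = AgeSchedule(counties=other, populations=np.ones((2, 9)))
        with pytest.raises(ValueError):
            cr.ypll75(draws, sched)
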