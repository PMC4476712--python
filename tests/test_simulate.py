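"""Generator determinism, degenerate limits, and moment-matching checks."""

import io
from dataclasses import replace

import numpy as np
import pytest
from scipy import special

import countyrank as cr
from countyrank.simulate import (
    AGE_JOINT,
    FPH_LBW_JOINT,
    INFANT_MORTALITY_LONGITUDINAL,
    _draw_effects,
)


class TestHierarchyGeneration:
    def test_constant_counties_product(self):
        h = cr.generate_hierarchy(51, 60, seed=1)
        assert h.n_states == 51
        assert h.n_counties == 51 * 60

    def test_single_county(self):
        h = cr.generate_hierarchy(1, 1, seed=99)
        assert h.county_keys == [("S01", "C001")]

    def test_seed_determinism(self):
        a = cr.generate_hierarchy(8, (3, 12), seed=4)
        b = cr.generate_hierarchy(8, (3, 12), seed=4)
        assert a == b
        c = cr.generate_hierarchy(8, (3, 12), seed=5)
        assert a != c

    def test_zero_states_rejected(self):
        with pytest.raises(ValueError):
            cr.generate_hierarchy(0, 5, seed=1)


class TestGeneratorParams:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            cr.GeneratorParams(alpha=0.0, sigma2_state=-0.1)

    def test_correlation_bounds(self):
        with pytest.raises(ValueError):
            cr.GeneratorParams(alpha=0.0, tau2_county=0.1, rho_county=1.5)

    def test_effect_covariance_matches_blocks(self, rng):
        # empirical covariance of (intercept, slope) draws converges to the
        # requested 2x2 block within Monte-Carlo error at 1e5 draws
        cov = INFANT_MORTALITY_LONGITUDINAL.level_cov("county")
        draws = _draw_effects(np.random.default_rng(11), 100_000, cov)
        emp = np.cov(draws.T)
        n = draws.shape[0]
        for i in range(2):
            for j in range(2):
                se = np.sqrt((cov[i, i] * cov[j, j] + cov[i, j] ** 2) / n)
                assert abs(emp[i, j] - cov[i, j]) < 3 * se


class TestMortalityPanel:
    def test_degenerate_rates_exact(self):
        p = cr.GeneratorParams(alpha=-5.0, n_states=3, counties_per_state=4)
        panel, truth = cr.simulate_mortality_panel(p, times=(0,), seed=2)
        assert np.allclose(truth["rate"], np.exp(-5.0))

    def test_byte_determinism(self):
        p = replace(INFANT_MORTALITY_LONGITUDINAL, n_states=4, counties_per_state=5)
        out = []
        for _ in range(2):
            panel, _ = cr.simulate_mortality_panel(p, seed=31)
            buf = io.StringIO()
            cr.write_panel(panel, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_marginal_mean_matches_lognormal_moment(self):
        # E[y/n] = E[rho] = exp(alpha + (s2_state + s2_county)/2) for the
        # intercept-only model; checked against the Monte-Carlo SE of the mean
        p = cr.GeneratorParams(
            alpha=-5.0, sigma2_state=0.04, sigma2_county=0.05,
            n_states=40, counties_per_state=250,
        )
        h = cr.generate_hierarchy(p.n_states, p.counties_per_state, seed=8)
        pops = np.full(h.n_counties, 1e5)
        panel, truth = cr.simulate_mortality_panel(
            p, times=(0,), seed=8, hierarchy=h, populations=pops
        )
        rates = panel.data["y"].to_numpy() / panel.data["n"].to_numpy()
        expected = np.exp(-5.0 + 0.5 * (0.04 + 0.05))
        # counties within a state share its random effect, so the independent
        # Monte-Carlo units are the 40 state means (cluster standard error)
        state_means = (
            panel.data.assign(rate=rates).groupby("state")["rate"].mean().to_numpy()
        )
        se = state_means.std(ddof=1) / np.sqrt(len(state_means))
        assert abs(rates.mean() - expected) < 3 * se

    def test_truth_rates_positive(self):
        panel, truth = cr.simulate_mortality_panel(
            replace(INFANT_MORTALITY_LONGITUDINAL, n_states=4, counties_per_state=6),
            seed=13,
        )
        assert (truth["rate"] > 0).all()

    def test_age_mode_shapes(self):
        p = replace(AGE_JOINT, n_states=3, counties_per_state=4)
        panel, truth = cr.simulate_mortality_panel(
            p, times=None, ages=tuple(range(1, 10)), seed=6
        )
        assert panel.n_records == 3 * 4 * 9
        assert set(truth["age"]) == set(range(1, 10))
        assert (truth["rate"] > 0).all()


class TestSurveyMeans:
    def test_noiseless_limit(self):
        p = cr.GeneratorParams(
            alpha=1.2, beta=-0.07, sigma2_county=0.04, tau2_county=0.04,
            sigma2_state=0.02, tau2_state=0.002, n_states=4, counties_per_state=5,
        )
        panel, truth = cr.simulate_survey_means(p, seed=3, se_range=(1e-9, 1.1e-9))
        merged = panel.data.merge(truth, on=["state", "county", "measure"],
                                  suffixes=("_obs", "_true"))
        assert np.allclose(merged["mean_obs"], merged["mean_true"], rtol=1e-5)

    def test_variance_decomposition(self):
        # var(log observed mean) = s2_state + s2_county + E[s^2] across counties
        p = cr.GeneratorParams(
            alpha=1.24, sigma2_county=0.05, sigma2_state=0.02,
            n_states=50, counties_per_state=60,
        )
        panel, _ = cr.simulate_survey_means(p, seed=17, se_range=(0.05, 0.15))
        df = panel.data[panel.data["measure"] == 0]
        log_m = np.log(df["mean"].to_numpy())
        s = df["se"].to_numpy() / df["mean"].to_numpy()
        expected = 0.05 + 0.02 + np.mean(s**2)
        n = len(log_m)
        se_var = expected * np.sqrt(2.0 / n) * 2  # loose MC band (non-normal mix)
        assert abs(np.var(log_m, ddof=1) - expected) < 3 * se_var


class TestBinomialPair:
    def test_degenerate_probabilities(self):
        p = cr.GeneratorParams(alpha=-1.70, beta=-0.80, n_states=3, counties_per_state=4)
        panel, truth = cr.simulate_binomial_pair(p, seed=5)
        pi0 = truth.loc[truth["measure"] == 0, "p"].to_numpy()
        pi1 = truth.loc[truth["measure"] == 1, "p"].to_numpy()
        assert np.allclose(pi0, special.expit(-1.70))
        assert np.allclose(pi1, special.expit(-2.50))
        assert special.expit(-1.70) == pytest.approx(0.1545, abs=5e-5)
        assert special.expit(-2.50) == pytest.approx(0.0759, abs=5e-5)

    def test_unit_denominator_counts_binary(self):
        p = replace(FPH_LBW_JOINT, n_states=3, counties_per_state=5)
        h = cr.generate_hierarchy(3, 5, seed=2)
        dens = np.ones((h.n_counties, 2), dtype=int)
        panel, _ = cr.simulate_binomial_pair(p, seed=2, hierarchy=h, denominators=dens)
        assert set(panel.data["y"]).issubset({0, 1})

    def test_pooled_mean_matches_expectation(self):
        p = cr.GeneratorParams(
            alpha=-1.7, sigma2_state=0.06, sigma2_county=0.07,
            n_states=40, counties_per_state=50,
        )
        h = cr.generate_hierarchy(40, 50, seed=4)
        dens = np.full((h.n_counties, 2), 200, dtype=int)
        panel, truth = cr.simulate_binomial_pair(p, seed=4, hierarchy=h, denominators=dens)
        df = panel.data[panel.data["measure"] == 0]
        obs = df["p"].to_numpy()
        # E[pi] via quadrature over the Gaussian linear predictor
        x, w = np.polynomial.hermite.hermgauss(60)
        sd = np.sqrt(0.06 + 0.07)
        epi = np.sum(w * special.expit(-1.7 + np.sqrt(2) * sd * x)) / np.sqrt(np.pi)
        state_means = df.groupby("state")["p"].mean().to_numpy()
        se = state_means.std(ddof=1) / np.sqrt(len(state_means))
        assert abs(obs.mean() - epi) < 3 * se
        assert ((truth["p"] > 0) & (truth["p"] < 1)).all()


class TestMissingness:
    def test_rate_zero_unchanged(self):
        panel, _ = cr.simulate_binomial_pair(
            replace(FPH_LBW_JOINT, n_states=3, counties_per_state=4), seed=1)
        out = cr.inject_missingness(panel, rate=0.0, seed=1)
        assert not out.data["suppressed"].any()

    def test_rate_one_all_suppressed(self):
        panel, _ = cr.simulate_binomial_pair(
            replace(FPH_LBW_JOINT, n_states=3, counties_per_state=4), seed=1)
        out = cr.inject_missingness(panel, rate=1.0, seed=1)
        assert out.data["suppressed"].all()

    def test_suppressed_count_binomially_distributed(self):
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.05, sigma2_state=0.04,
                               n_states=10, counties_per_state=100)
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=7)
        counts = []
        for s in range(25):
            out = cr.inject_missingness(panel, rate=0.1, seed=s)
            counts.append(int(out.data["suppressed"].sum()))
        n = panel.n_records
        # each replicate within a 4-sigma binomial band, mean within 3 SE
        band = 4 * np.sqrt(n * 0.1 * 0.9)
        assert all(abs(c - 0.1 * n) < band for c in counts)
        assert abs(np.mean(counts) - 0.1 * n) < 3 * np.sqrt(n * 0.1 * 0.9 / len(counts))

    def test_rule_dispatch(self):
        panel, _ = cr.simulate_mortality_panel(
            cr.GeneratorParams(alpha=-8.0, sigma2_county=0.05, sigma2_state=0.04,
                               n_states=3, counties_per_state=10,
                               pop_range=(300, 3000)),
            times=(0,), seed=3)
        out = cr.inject_missingness(panel, rule="vital")
        assert out.data["suppressed"].equals(panel.data["y"] <= 5)
        with pytest.raises(ValueError):
            cr.inject_missingness(panel, rate=0.5, rule="vital")
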