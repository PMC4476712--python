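"""Fitting: degenerate limits, closed-form EB agreement, nesting relations,
shrinkage behavior, and single-panel recovery smoke checks."""

import io
from dataclasses import replace

import numpy as np
import pytest

import countyrank as cr
from _oracles import gaussian_eb_oracle


def survey_panel_from(df_rows):
    header = "state,county,fips,measure,mean,se,n_resp\n"
    rows = "\n".join(",".join(map(str, r)) for r in df_rows)
    return cr.read_panel(io.StringIO(header + rows), "survey_mean")


class TestModelSpec:
    def test_joint_age_requires_poisson(self):
        with pytest.raises(ValueError):
            cr.ModelSpec(family="binomial", design="joint_age")

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            cr.ModelSpec(family="gamma", design="cross_sectional")


class TestGaussianCrossSectional:
    def test_degenerate_equal_observations(self):
        rows = [("S01", "C001", "", 0, 4.0, 0.2, 100),
                ("S01", "C002", "", 0, 4.0, 0.2, 100),
                ("S02", "C001", "", 0, 4.0, 0.2, 100),
                ("S02", "C002", "", 0, 4.0, 0.2, 100)]
        fit = cr.fit_cross_sectional(survey_panel_from(rows), "normal_known_variance")
        assert fit.fixed[0] == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.vc.state_cov[0, 0] < 1e-5
        assert fit.vc.county_cov[0, 0] < 1e-5
        assert np.abs(fit.eb_mean_county).max() < 1e-4
        assert np.abs(fit.eb_mean_state).max() < 1e-4

    def test_eb_means_match_gls_closed_form(self, normal_cross_fit):
        # the EB conditional mean must equal the precision-weighted shrinkage
        # solution of the Gaussian model at the fitted variance components
        panel, _, fit = normal_cross_fit
        df = panel.active().sort_values(["state", "county"])
        m = df["mean"].to_numpy()
        se = df["se"].to_numpy()
        z = np.log(m)
        s2 = (se / m) ** 2
        eb_s, eb_c = gaussian_eb_oracle(
            z, s2, df["state"].to_numpy(),
            fit.fixed[0], fit.vc.state_cov[0, 0], fit.vc.county_cov[0, 0],
        )
        assert np.abs(fit.eb_mean_state[:, 0] - eb_s).max() < 1e-8
        assert np.abs(fit.eb_mean_county[:, 0] - eb_c).max() < 1e-8

    def test_loglik_not_below_start(self, normal_cross_fit):
        # the optimizer must never return a point worse than its start
        panel, _, fit = normal_cross_fit
        from countyrank.fit import _roster_arrays
        from countyrank.laplace import CovStructure, NestedGLMM

        roster, cidx, _, county_state = _roster_arrays(panel)
        df = panel.active()
        m = df["mean"].to_numpy()
        se = df["se"].to_numpy()
        county = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
        X = np.ones((len(df), 1))
        model = NestedGLMM(X, X.copy(), np.log(m), (se / m) ** 2, county, county_state,
                           "normal_known_variance", CovStructure("scalar", 1),
                           CovStructure("scalar", 1))
        start = model.marginal_loglik(
            model._beta_start(), model.struct_c.init(), model.struct_s.init()
        )
        assert fit.loglik >= start


class TestPoissonFits:
    def test_all_suppressed_panel_errors(self):
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.04, sigma2_state=0.03,
                               n_states=3, counties_per_state=4)
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=1)
        panel = cr.inject_missingness(panel, rate=1.0, seed=0)
        with pytest.raises(ValueError):
            cr.fit_cross_sectional(panel, "poisson")

    def test_single_time_point_directed_to_cross_sectional(self):
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.04, sigma2_state=0.03,
                               n_states=3, counties_per_state=4)
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=1)
        with pytest.raises(ValueError, match="cross_sectional|cross-sectional"):
            cr.fit_longitudinal(panel)

    def test_cross_sectional_single_panel_recovery(self):
        p = cr.GeneratorParams(alpha=-5.00, sigma2_county=0.046, sigma2_state=0.039,
                               n_states=51, counties_per_state=20,
                               pop_range=(1e4, 1e6))
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=23)
        fit = cr.fit_cross_sectional(panel, "poisson")
        assert fit.converged
        assert fit.fixed[0] == pytest.approx(-5.00, abs=0.12)
        assert fit.vc.county_cov[0, 0] == pytest.approx(0.046, abs=0.02)
        assert fit.vc.state_cov[0, 0] == pytest.approx(0.039, abs=0.03)

    def test_longitudinal_near_zero_slope_variance(self):
        # truth has no trend heterogeneity: fitted slope variances collapse
        p = cr.GeneratorParams(alpha=-5.0, beta=0.0, sigma2_county=0.05,
                               tau2_county=0.0, sigma2_state=0.04, tau2_state=0.0,
                               n_states=20, counties_per_state=15,
                               pop_range=(1e4, 1e6))
        panel, _ = cr.simulate_mortality_panel(p, seed=14)
        fit = cr.fit_longitudinal(panel, polish=False)
        assert fit.vc.county_cov[1, 1] < 5e-4
        assert fit.vc.state_cov[1, 1] < 5e-4
        assert fit.fixed[1] == pytest.approx(0.0, abs=0.01)

    def test_eb_shrinkage_monotone_in_population(self):
        # counties observed at twice the background rate: the EB intercept
        # moves toward the observed deviation as the denominator grows
        rows = []
        base_rate, high_rate = 0.01, 0.02
        for i in range(12):
            rows.append(f"S01,B{i:03d},,0,{int(base_rate * 200000)},200000")
        ns = [200, 2000, 20000, 200000]
        for j, n in enumerate(ns):
            rows.append(f"S01,T{j:03d},,0,{int(high_rate * n)},{n}")
        header = "state,county,fips,t_or_age,y,n\n"
        panel = cr.read_panel(io.StringIO(header + "\n".join(rows)), "counts")
        fit = cr.fit_cross_sectional(panel, "poisson")
        keys = {key: i for i, key in enumerate(fit.roster)}
        devs = [fit.eb_mean_county[keys[("S01", f"T{j:03d}")], 0] for j in range(len(ns))]
        assert all(d2 > d1 for d1, d2 in zip(devs, devs[1:]))


class TestJointAge:
    def test_fixed_effect_collapse_single_state(self):
        # no random variation: age contrasts are the log rate ratios of the
        # pooled national rates against the infant reference
        rng = np.random.default_rng(5)
        rows = []
        true_rates = np.array([0.007, 0.0004, 0.0003, 0.001, 0.0012,
                               0.002, 0.0045, 0.01, 0.022])
        n = 500_000
        for j in range(15):
            for a in range(1, 10):
                y = rng.poisson(true_rates[a - 1] * n)
                rows.append(f"S01,C{j:03d},,{a},{y},{n}")
        header = "state,county,fips,t_or_age,y,n\n"
        panel = cr.read_panel(io.StringIO(header + "\n".join(rows)), "counts")
        fit = cr.fit_joint_age(panel, polish=False)
        df = panel.data
        pooled = df.groupby("t_or_age").apply(
            lambda g: g["y"].sum() / g["n"].sum(), include_groups=False
        )
        expected = np.log(pooled.loc[2:].to_numpy() / pooled.loc[1])
        assert np.abs(fit.fixed[1:] - expected).max() < 0.02

    def test_reference_rows_cover_nine_ages(self, small_hierarchy):
        p = replace(cr.simulate.AGE_JOINT, n_states=5, counties_per_state=10)
        panel, _ = cr.simulate_mortality_panel(
            p, times=None, ages=tuple(range(1, 10)), seed=3, hierarchy=small_hierarchy
        )
        fit = cr.fit_joint_age(panel, polish=False)
        refs = fit.reference_rows()
        assert list(refs) == [f"age_{a}" for a in range(1, 10)]
        assert refs["age_1"].tolist() == [1.0] + [0.0] * 8
        assert refs["age_9"][0] == 1.0 and refs["age_9"][8] == 1.0


@pytest.fixture(scope="module")
def bivariate_panel():
    p = cr.GeneratorParams(
        alpha=1.24, beta=-0.07, sigma2_county=0.038, tau2_county=0.038,
        rho_county=-0.313, sigma2_state=0.017, tau2_state=0.002,
        rho_state=0.086, n_states=15, counties_per_state=12,
    )
    return cr.simulate_survey_means(p, seed=29)


class TestJointBivariate:
    def test_reduces_to_univariate_without_second_measure(self, bivariate_panel):
        panel, _ = bivariate_panel
        df0 = panel.data[panel.data["measure"] == 0].reset_index(drop=True)
        panel0 = cr.GeoPanel(panel.hierarchy, df0, "survey_mean", panel.measure_name)
        uni = cr.fit_cross_sectional(panel0, "normal_known_variance")
        joint = cr.fit_joint_bivariate(panel0, "normal_known_variance")
        assert joint.fixed[0] == pytest.approx(uni.fixed[0], abs=1e-4)
        assert joint.vc.county_cov[0, 0] == pytest.approx(uni.vc.county_cov[0, 0], abs=1e-4)
        assert joint.vc.state_cov[0, 0] == pytest.approx(uni.vc.state_cov[0, 0], abs=1e-4)

    def test_single_panel_recovery(self, bivariate_panel):
        panel, _ = bivariate_panel
        fit = cr.fit_joint_bivariate(panel, "normal_known_variance")
        assert fit.converged
        assert fit.fixed[0] == pytest.approx(1.24, abs=0.12)
        assert fit.fixed[1] == pytest.approx(-0.07, abs=0.08)
        assert fit.vc.county_cov[0, 0] == pytest.approx(0.038, abs=0.03)

    def test_boundary_correlation_stays_finite(self):
        p = cr.GeneratorParams(
            alpha=-1.7, beta=-0.8, sigma2_county=0.06, tau2_county=0.06,
            rho_county=1.0, sigma2_state=0.05, tau2_state=0.05, rho_state=1.0,
            n_states=10, counties_per_state=10,
        )
        panel, _ = cr.simulate_binomial_pair(p, seed=8)
        fit = cr.fit_joint_bivariate(panel, "binomial", polish=False)
        assert np.all(np.isfinite(fit.fixed))
        assert np.all(np.isfinite(fit.vc.county_cov))
        rho = fit.vc.correlation("county")
        assert -1.0 <= rho <= 1.0
        assert rho > 0.6  # near the +1 boundary


class TestVarianceComponents:
    def test_variances_never_negative(self, longitudinal_fit):
        _, _, fit = longitudinal_fit
        assert (fit.vc.variances("state") >= 0).all()
        assert (fit.vc.variances("county") >= 0).all()
        for cov in (fit.eb_cov_county, fit.eb_cov_state):
            assert (np.linalg.eigvalsh(cov).min(axis=-1) > -1e-10).all()

    def test_every_county_has_eb_block(self, longitudinal_fit):
        panel, _, fit = longitudinal_fit
        assert fit.eb_mean_county.shape[0] == panel.hierarchy.n_counties
        assert len(fit.roster) == panel.hierarchy.n_counties

    def test_suppressed_county_gets_prior_block(self):
        p = cr.GeneratorParams(alpha=-5.0, sigma2_county=0.04, sigma2_state=0.03,
                               n_states=4, counties_per_state=8,
                               pop_range=(1e4, 1e5))
        panel, _ = cr.simulate_mortality_panel(p, times=(0,), seed=10)
        df = panel.data.copy()
        df.loc[(df["state"] == "S01") & (df["county"] == "C001"), "suppressed"] = True
        panel = cr.GeoPanel(panel.hierarchy, df, "counts", panel.measure_name)
        fit = cr.fit_cross_sectional(panel, "poisson")
        i = fit.roster.index(("S01", "C001"))
        assert fit.eb_mean_county[i, 0] == pytest.approx(0.0, abs=1e-10)
        assert fit.eb_cov_county[i, 0, 0] == pytest.approx(
            fit.vc.county_cov[0, 0], rel=1e-8
        )


class TestPersistence:
    def test_fit_json_round_trip(self, tmp_path, normal_cross_fit):
        _, _, fit = normal_cross_fit
        path = tmp_path / "fit.json"
        cr.save_fit(fit, path)
        back = cr.load_fit(path)
        assert back.spec == fit.spec
        np.testing.assert_array_equal(back.fixed, fit.fixed)
        np.testing.assert_array_equal(back.eb_mean_county, fit.eb_mean_county)
        np.testing.assert_array_equal(back.eb_cov_state, fit.eb_cov_state)
        assert back.roster == fit.roster
        assert back.loglik == fit.loglik
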