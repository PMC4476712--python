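import numpy as np
import pytest
from dataclasses import replace
from hypothesis import settings

import countyrank as cr
from countyrank.simulate import INFANT_MORTALITY_LONGITUDINAL

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_hierarchy():
    return cr.generate_hierarchy(5, 10, seed=7)


@pytest.fixture(scope="session")
def longitudinal_fit():
    """One moderate longitudinal mortality fit reused across test modules."""
    params = replace(
        INFANT_MORTALITY_LONGITUDINAL, n_states=15, counties_per_state=12,
        pop_range=(1e3, 1e5),
    )
    panel, truth = cr.simulate_mortality_panel(params, seed=42)
    fit = cr.fit_longitudinal(panel, polish=False)
    return panel, truth, fit


@pytest.fixture(scope="session")
def normal_cross_fit():
    """Univariate known-variance Gaussian fit on a 120-county panel."""
    params = cr.GeneratorParams(
        alpha=1.24, sigma2_county=0.048, sigma2_state=0.021,
        n_states=12, counties_per_state=10,
    )
    panel, truth = cr.simulate_survey_means(params, seed=9)
    df = panel.data[panel.data["measure"] == 0].reset_index(drop=True)
    panel0 = cr.GeoPanel(panel.hierarchy, df, "survey_mean", "days")
    fit = cr.fit_cross_sectional(panel0, "normal_known_variance")
    return panel0, truth, fit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
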