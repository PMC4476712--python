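#!/usr/bin/env python
"""Generate one synthetic county panel per model class and tabulate what the
suppression rules would remove.

Writes the panels (longitudinal mortality, joint age-group mortality,
survey-mean pair, binomial pair) under results/panels/ together with their
latent truth, and a summary of roster sizes and suppression counts. The
generating parameters are the package defaults, which mirror the fitted
values of the real county health application, so the panels carry realistic
scale and small-county sparsity.
"""

from pathlib import Path

import pandas as pd

import countyrank as cr
from countyrank.simulate import (
    AGE_JOINT,
    FPH_LBW_JOINT,
    HEALTH_DAYS_JOINT,
    INFANT_MORTALITY_LONGITUDINAL,
)
from dataclasses import replace

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "panels"  # full panels are regenerable bulk
RES = ROOT / "results"
OUT.mkdir(parents=True, exist_ok=True)
RES.mkdir(parents=True, exist_ok=True)
SEED = 20260923

rows = []

configs = {
    "mortality_longitudinal": (
        lambda: cr.simulate_mortality_panel(
            replace(INFANT_MORTALITY_LONGITUDINAL, n_states=20, counties_per_state=15),
            seed=SEED),
        "vital",
    ),
    "mortality_joint_age": (
        lambda: cr.simulate_mortality_panel(
            replace(AGE_JOINT, n_states=10, counties_per_state=10),
            times=None, ages=tuple(range(1, 10)), seed=SEED + 1),
        "vital",
    ),
    "health_days_pair": (
        lambda: cr.simulate_survey_means(
            replace(HEALTH_DAYS_JOINT, n_states=20, counties_per_state=15),
            seed=SEED + 2),
        "brfss",
    ),
    "prevalence_pair": (
        lambda: cr.simulate_binomial_pair(
            replace(FPH_LBW_JOINT, n_states=20, counties_per_state=15),
            seed=SEED + 3),
        "brfss",
    ),
}

for name, (maker, rule) in configs.items():
    panel, truth = maker()
    flagged = cr.inject_missingness(panel, rule=rule)
    cr.write_panel(flagged, OUT / f"{name}.csv")
    truth.to_csv(OUT / f"{name}_truth.csv", index=False)
    n_sup = int(flagged.data["suppressed"].sum())
    rows.append(
        {
            "panel": name,
            "counties": panel.hierarchy.n_counties,
            "records": panel.n_records,
            "suppressed_records": n_sup,
            "suppressed_pct": 100.0 * n_sup / panel.n_records,
        }
    )
    print(f"{name}: {panel.n_records} records, "
          f"{n_sup} suppressed ({100.0 * n_sup / panel.n_records:.1f}%)")

pd.DataFrame(rows).to_csv(RES / "panel_summary.csv", index=False)
print(f"\npanels written to {OUT}")
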