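#!/usr/bin/env python
"""Compare rank quartile certainty across model classes.

Two replicate studies: (1) longitudinal vs cross-sectional Poisson fits on
trending mortality panels with noisy current-period counts — pooling four
periods should raise the share of counties placed in their assigned
national quartile with high certainty (p >= 0.75); (2) joint vs univariate
binomial fits when the two measures are unrelated — precision should move
by less than a percentage point either way. Writes the per-replicate
numbers and a high-certainty report table.
"""

from pathlib import Path

from scipy import stats

import countyrank.studies as studies

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260923

trend = studies.trend_precision_study(n_reps=10, seed=SEED)
trend.to_csv(OUT / "trend_precision.csv", index=False)
wins = int((trend["difference"] > 0).sum())
p = stats.binomtest(wins, len(trend), 0.5, alternative="greater").pvalue
print("longitudinal vs cross-sectional (trending mortality panels):")
print(f"  high-certainty share: {trend['pct_high_longitudinal'].mean():.1f}% vs "
      f"{trend['pct_high_cross_sectional'].mean():.1f}% "
      f"(mean gain {trend['difference'].mean():+.1f} pp)")
print(f"  longitudinal better in {wins}/{len(trend)} replicates "
      f"(one-sided sign test p = {p:.2g})")

joint = studies.independent_joint_study(n_reps=10, seed=SEED + 1)
joint.to_csv(OUT / "independent_joint_precision.csv", index=False)
print("\njoint vs univariate (unrelated binomial measures):")
print(f"  mean paired difference in assigned-quartile probability: "
      f"{joint['mean_paired_diff_pp'].mean():+.2f} pp "
      f"(|diff| < 1 pp: neither improvement nor degradation)")
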