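#!/usr/bin/env python
"""Figures and derived analytics for the simulated campaigns.

Reads the campaign outputs of 04_run_campaigns.py and produces the
round-wise boxplot, the 96 h vs 168 h correlation scatter, the importance
bars and the changing-ratio table under results/figures/.
"""

from pathlib import Path

import medopt as m
from medopt.reporting import plot_importance, plot_round_boxplots, plot_timepoint_scatter

ROOT = Path(__file__).resolve().parent.parent / "results"
FIG = ROOT / "figures"
FIG.mkdir(parents=True, exist_ok=True)

space = m.build_design_space()
oracle = m.make_default_oracle(space, rng_seed=0)

# recreate the regular-mode campaign (seeded, so identical to 04's output)
config = m.CampaignConfig(
    mode="regular", n_rounds=4, batch_size=19, candidate_cap=10_000, seed=1,
    grid=m.HyperParamGrid.reduced(), evaluate_cv=False,
    compute_importance=True, importance_replicates=5,
)
res = m.run_campaign(space, oracle, config)
ds = res.dataset

ref = ds.mean_a450(168.0, ["baseline"]).iloc[0]
plot_round_boxplots(res, ref, FIG / "rounds_boxplot.png")
plot_timepoint_scatter(ds, 96.0, 168.0, FIG / "scatter_96h_168h.png")
plot_importance(res.importance, FIG / "importance.png")

ratios = m.changing_ratio(ds, 96.0, 168.0)
ratios.to_csv(FIG / "changing_ratio_96_168.csv")
rho, p = m.timepoint_correlation(ds, 96.0, 168.0)

print(f"wrote {sorted(p.name for p in FIG.iterdir())}")
print(f"Spearman rho(96h, 168h) over the full campaign dataset: {rho:.3f} (p={p:.2g})")
print(f"media with flagged (non-positive 96h) changing ratios: {int(ratios['flagged'].sum())}")
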