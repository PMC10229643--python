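#!/usr/bin/env python
"""Measure the OFAT design through the synthetic oracle.

Simulates triplicate A450 timecourses (48/96/144/168 h) for every initial
medium, writes the dataset table, and reports the rank coupling between
timepoints that motivates the time-saving mode.
"""

from pathlib import Path

import medopt as m
from medopt.io_tables import save_oracle

OUT = Path(__file__).resolve().parent.parent / "results"
(OUT / "datasets").mkdir(parents=True, exist_ok=True)

space = m.build_design_space()
oracle = m.make_default_oracle(space, rng_seed=0)
save_oracle(oracle, OUT / "datasets" / "oracle.yaml")

design = m.generate_initial_design(space)
ds = m.build_dataset(oracle, design, n_replicates=3, rng_seed=1)
m.write_dataset(ds, OUT / "datasets" / "initial_dataset.csv")

best_id, best = ds.best(168.0)
print(f"simulated {len(ds)} media x {len(ds.timepoints)} timepoints x 3 replicates")
print(f"baseline (EMEM) A450@168h: {ds.mean_a450(168.0)['baseline']:.3f}")
print(f"best OFAT medium: {best_id} (A450@168h = {best:.3f})")
for t in (48.0, 96.0, 144.0):
    rho, p = m.timepoint_correlation(ds, t, 168.0)
    print(f"Spearman rho(A450@{t:g}h, A450@168h) = {rho:.3f} (p = {p:.2g})")
print("-> the 96 h readout preserves most of the 168 h ranking; 48 h does not,")
print("   which is why the time-saving mode trains on 96 h data.")
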