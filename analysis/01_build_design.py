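#!/usr/bin/env python
"""Build the EMEM composition space and the OFAT initial design.

Writes the component table, the initial design (one medium per component x
non-baseline level, plus the all-baseline control) and a sampled candidate
pool to results/design/.
"""

from pathlib import Path

import pandas as pd

import medopt as m
from medopt.io_tables import write_component_table

OUT = Path(__file__).resolve().parent.parent / "results" / "design"
OUT.mkdir(parents=True, exist_ok=True)

space = m.build_design_space()
write_component_table(m.default_component_table(), OUT / "components.csv")

design = m.generate_initial_design(space)
pd.DataFrame(
    [{"id": c.id, **dict(zip(space.names, c.folds))} for c in design]
).to_csv(OUT / "initial_design.csv", index=False)

pool = m.sample_candidates(space, 2000, rng_seed=0, exclude=design, max_changes=4)
pd.DataFrame([dict(zip(space.names, c.folds)) for c in pool]).to_csv(
    OUT / "candidate_sample.csv", index=False
)

print(f"space: {space.n_components} components, {space.tunable_count} tunable")
print(f"full level grid: {space.grid_size:.3e} media")
print(f"OFAT initial design: {len(design)} media -> {OUT/'initial_design.csv'}")
print(f"candidate sample (<=4 altered components): {len(pool)} media")
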