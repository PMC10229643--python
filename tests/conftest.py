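import pandas as pd
import pytest

import medopt as m


@pytest.fixture(scope="session")
def space():
    """Default EMEM-based design space (31 components, 29 tunable)."""
    return m.build_design_space()


@pytest.fixture(scope="session")
def toy_space():
    """Three tunable five-level components plus one fixed component."""
    table = pd.DataFrame(
        {
            "name": ["A", "B", "C", "FIX"],
            "baseline": [1.0, 2.0, 5.0, 0.5],
            "unit": ["mM", "mM", "mM", "mM"],
            "levels": ["0;0.1;1;10;100"] * 3 + ["1"],
            "fixed": [False, False, False, True],
            "role": ["other"] * 4,
        }
    )
    return m.build_design_space(table)


@pytest.fixture(scope="session")
def oracle(space):
    return m.make_default_oracle(space, rng_seed=0)


@pytest.fixture(scope="session")
def quiet_oracle(space):
    """Default effects with small replicate noise, for learnability checks."""
    return m.make_default_oracle(space, rng_seed=0, noise_sd_mult=0.02, noise_sd_add=0.005)


@pytest.fixture(scope="session")
def ofat_dataset(space, oracle):
    """Simulated measurements of the full OFAT initial design (112 media)."""
    design = m.generate_initial_design(space)
    return m.build_dataset(oracle, design, n_replicates=3, rng_seed=11)


@pytest.fixture(scope="session")
def reduced_grid():
    return m.HyperParamGrid.reduced()
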