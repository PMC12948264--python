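import numpy as np
import pytest

import pocrmkit as pk


@pytest.fixture(scope="session")
def table1_poset():
    """The 12-combination poset of the motivating three-drug trial."""
    return pk.motivating_poset()


@pytest.fixture(scope="session")
def all_orderings(table1_poset):
    """All 148 complete orderings of the motivating poset."""
    return pk.enumerate_linear_extensions(table1_poset)


@pytest.fixture(scope="session")
def scenarios12():
    """The 12 bundled benchmark toxicity scenarios."""
    return pk.table3_scenarios()


@pytest.fixture(scope="session")
def order_scenarios47(table1_poset):
    return pk.enumerate_order_scenarios(table1_poset)


@pytest.fixture(scope="session")
def r2_order_scenario(scenarios12):
    return pk.order_scenario_of(scenarios12[1], 0.25)


def random_subposet(levels, size, seed):
    """A random induced subposet of a grid, for oracle-equivalence checks."""
    full = pk.build_grid_poset(levels)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(full), size=size, replace=False)
    return pk.build_grid_poset(levels, [full.elements[i] for i in sorted(keep)])
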