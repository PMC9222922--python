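import pytest

from retrotraffic import analyze_clade, simulate_clade, simulate_expression
from retrotraffic.synthetic_data import SimScenario


@pytest.fixture(scope="session")
def scenario():
    return SimScenario(seed=1)


@pytest.fixture(scope="session")
def world(scenario):
    """Default synthetic clade: 12 species, 9 planted events, 3 decoys."""
    annotations, tree, ledger = simulate_clade(scenario)
    return annotations, tree, ledger


@pytest.fixture(scope="session")
def staged_pairs(world):
    annotations, tree, _ledger = world
    return analyze_clade(annotations, tree)


@pytest.fixture(scope="session")
def expression(scenario, world):
    annotations, _tree, ledger = world
    matrices = simulate_expression(scenario, ledger, annotations[scenario.focal_species])
    return matrices, ledger
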