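import numpy as np
import pytest

from seedscape.diffexpr import DifferentialExpression, rank_genes
from seedscape.simulate import paper_scenario
from seedscape.utrs import count_words


@pytest.fixture(scope="session")
def scenario():
    """One full simulated study shared by read-only tests."""
    return paper_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_counts(scenario):
    return count_words(scenario.utrs, scenario.lexicon.dna_words())


@pytest.fixture(scope="session")
def mimic_de(scenario):
    return DifferentialExpression(scenario.expression).fit(("mimic", "inhibitor"))


@pytest.fixture(scope="session")
def mimic_ranking(mimic_de):
    return rank_genes(mimic_de)
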