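import numpy as np
import pytest

from troutrisk import packaged_trait_table, compute_risk_scores

# Printed totals of the packaged 35-species screening matrix, in row order.
GOLDEN_TOTALS = [26, 25, 25, 25, 24, 23, 23, 23, 23, 23, 22, 22, 21, 21, 21,
                 20, 20, 19, 18, 18, 17, 17, 17, 17, 17, 16, 16, 16, 16, 15,
                 15, 15, 14, 14, 12]

# Published tier assignment: the 12 highest totals are High, the next 8
# Moderate, the remaining 15 Minor.
GOLDEN_TIER_COUNTS = {"High": 12, "Moderate": 8, "Minor": 15}


@pytest.fixture(scope="session")
def screening_matrix():
    return packaged_trait_table()


@pytest.fixture(scope="session")
def matrix_totals(screening_matrix):
    return {r.species: r.total for r in compute_risk_scores(screening_matrix)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20_250_101)
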