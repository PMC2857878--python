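import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import sigconnect as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def ten_gene_ranking():
    """Ranking of 10 genes with scores (5, 4, 3, 2, 1, -1, -2, -3, -4, -5)."""
    scores = [5, 4, 3, 2, 1, -1, -2, -3, -4, -5]
    return sc.RankedList([f"g{i}" for i in range(10)], scores)


@pytest.fixture
def toy_paired_matrix():
    """3 features x 3 patient pairs with hand-computable statistics."""
    values = pd.DataFrame(
        {
            "p1_LS": [8.0, 5.0, 4.0],
            "p1_NL": [6.0, 5.5, 4.0],
            "p2_LS": [9.0, 5.2, 4.1],
            "p2_NL": [6.5, 5.6, 4.1],
            "p3_LS": [8.5, 5.1, 3.9],
            "p3_NL": [6.2, 5.4, 3.9],
        },
        index=["up_gene", "flat_gene", "null_gene"],
    )
    pairs = [("p1", "p1_LS", "p1_NL"), ("p2", "p2_LS", "p2_NL"),
             ("p3", "p3_LS", "p3_NL")]
    return sc.PairedExpressionMatrix(values, pairs)


def random_ranking(rng, n, scale=2.0):
    scores = rng.normal(0.0, scale, size=n)
    return sc.build_ranked_list({f"g{i:05d}": s for i, s in enumerate(scores)})


@pytest.fixture
def make_ranking(rng):
    return lambda n, scale=2.0: random_ranking(rng, n, scale)
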