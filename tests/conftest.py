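import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pairodds import PairContingency, SurveyTable
from pairodds.contingency import DirectedPair


@pytest.fixture
def worked_table() -> PairContingency:
    """The illustrative 2x2 table (percent scale): both 15, A-only 35,
    B-only 5, neither 45 — species A at 50% presence, B at 20%."""
    return PairContingency(15, 35, 5, 45)


@pytest.fixture
def ab_pair() -> DirectedPair:
    return DirectedPair(predictor="B", target="A")


def realize_table(c: int, d: int, e: int, f: int) -> SurveyTable:
    """Survey table whose (A, B) contingency counts are exactly (c, d, e, f)."""
    cat = np.repeat([0, 1, 2, 3], [c, d, e, f])
    a = (cat <= 1).astype(np.int8)
    b = ((cat == 0) | (cat == 2)).astype(np.int8)
    return SurveyTable(pd.DataFrame({"A": a, "B": b}))


def clustered_pair_data(
    n_sites: int,
    surveys_per_site: int,
    b: float,
    beta0: float,
    beta1: float,
    sigma: float,
    rng: np.random.Generator,
) -> SurveyTable:
    """Two-species data from the random-site-intercept logistic process:
    predictor ~ Bernoulli(b), logit P(target) = beta0 + beta1 x + u_site."""
    site = np.repeat(np.arange(n_sites), surveys_per_site)
    x = (rng.random(len(site)) < b).astype(np.int8)
    u = rng.normal(0.0, sigma, n_sites)
    y = (rng.random(len(site)) < expit(beta0 + beta1 * x + u[site])).astype(np.int8)
    return SurveyTable(pd.DataFrame({"pred": x, "targ": y}), sites=site)


def small_tables(max_total: int):
    """All 2x2 tables (c, d, e, f) of non-negative ints with 0 < total <= max_total."""
    for total in range(1, max_total + 1):
        for c in range(total + 1):
            for d in range(total - c + 1):
                for e in range(total - c - d + 1):
                    yield c, d, e, total - c - d - e
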