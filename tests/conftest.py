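import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smht

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_sim():
    """Clean 3-factor simple-structure draw (n=500, p=18, loadings 0.7)."""
    cfg = smht.SimulationConfig(
        n_respondents=500,
        n_items=18,
        n_factors=3,
        loading_pattern=smht.simple_structure_loadings(18, 3, 0.7),
        uniqueness=1 - 0.7**2,
        seed=123,
    )
    return smht.simulate_responses(cfg)


@pytest.fixture(scope="session")
def independent_sim():
    """Large draw with zero loadings: items mutually independent (n=2000)."""
    cfg = smht.SimulationConfig(
        n_respondents=2000,
        n_items=12,
        n_factors=1,
        loading_pattern=np.zeros((12, 1)),
        uniqueness=1.0,
        seed=321,
    )
    return smht.simulate_responses(cfg)


@pytest.fixture(scope="session")
def structured_2000():
    """Structured base at n=2000 for retest/criterion recovery checks."""
    cfg = smht.SimulationConfig(
        n_respondents=2000,
        n_items=18,
        n_factors=3,
        loading_pattern=smht.simple_structure_loadings(18, 3, 0.7),
        uniqueness=1 - 0.7**2,
        seed=777,
    )
    return smht.simulate_responses(cfg)


@pytest.fixture(scope="session")
def sentiment_corpus():
    """Balanced three-class corpus from the built-in unigram models."""
    return smht.simulate_corpus(
        smht.default_class_unigrams(), docs_per_class=100, doc_length=30, seed=9
    )
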