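import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mesobloom import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_scenario():
    """Default 7-bag scenario without measurement noise."""
    return synthetic.MesocosmScenario(noise_cv=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_abundances(clean_scenario):
    return synthetic.generate_abundances(clean_scenario)


@pytest.fixture(scope="session")
def clean_chemistry(clean_scenario, clean_abundances):
    return synthetic.generate_bulk_chemistry(clean_abundances, clean_scenario)


@pytest.fixture(scope="session")
def noisy_scenario():
    return synthetic.MesocosmScenario(noise_cv=0.1, seed=7)


def two_taxon_matrix(similarities, days, bag="bag1", p0=0.95):
    """Two-taxon composition whose Bray-Curtis similarity curve against the
    first day equals ``similarities`` exactly (construction: BC between
    (p, 1-p) and (p0, 1-p0) is 1 - |p - p0|)."""
    from mesobloom.tables_io import CompositionMatrix

    similarities = np.asarray(similarities, dtype=float)
    p = p0 - (1.0 - similarities)
    cols = pd.MultiIndex.from_product([[bag], days], names=["bag", "day"])
    data = pd.DataFrame(np.vstack([p, 1.0 - p]), index=["A", "B"], columns=cols)
    return CompositionMatrix(data)
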